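"""Radioligand homologous-competition binding: model, fitting and dissection.

A trace concentration H of labelled toxin competes with increasing
concentrations C of the same unlabelled toxin for a single class of sites.
Under the no-depletion assumption with equi-affine hot and cold ligand the
bound signal is

    B(C) = Rt * H / (Kd + H + C) + NS * H

where Kd is the equilibrium dissociation constant (nM), Rt the concentration
of binding sites (pmol/mg of vesicle protein) and NS the nonspecific binding
expressed as a dimensionless fraction of the free hot ligand.

The module also implements the three-sample dissection of specific binding
into reversible and irreversible components, and a seeded curve simulator for
parameter-recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingCurve",
    "BindingFit",
    "DissectionResult",
    "model_bound",
    "fit_homologous_competition",
    "dissect_binding",
    "simulate_binding_curve",
]


@dataclass(frozen=True)
class BindingCurve:
    """One homologous-competition curve.

    ``hot`` is the labelled-ligand concentration (nM, constant over the
    curve), ``conc`` the competitor concentrations (nM) and ``bound`` the
    bound signal at each concentration (pmol/mg).
    """

    hot: float
    conc: np.ndarray
    bound: np.ndarray
    protein_ug: float | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        bound = np.asarray(self.bound, dtype=float)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "bound", bound)
        if self.hot <= 0:
            raise ValueError("hot ligand concentration must be > 0")
        if conc.shape != bound.shape:
            raise ValueError("conc and bound must have the same shape")
        if (conc < 0).any():
            raise ValueError("competitor concentrations must be >= 0")

    def n_distinct(self) -> int:
        return int(np.unique(self.conc).size)


@dataclass(frozen=True)
class BindingFit:
    """Fitted one-site homologous-competition parameters."""

    kd: float
    rt: float
    ns: float
    se_kd: float
    se_rt: float
    se_ns: float
    converged: bool
    degenerate: bool = False


@dataclass(frozen=True)
class DissectionResult:
    """Specific binding split into reversible and irreversible components.

    Satisfies ``reversible + irreversible == specific`` by construction.
    """

    total: float
    nonspecific: float
    irreversible_sample: float
    specific: float = field(init=False)
    irreversible: float = field(init=False)
    reversible: float = field(init=False)

    def __post_init__(self) -> None:
        specific = self.total - self.nonspecific
        irreversible = self.irreversible_sample - self.nonspecific
        clamped = False
        if specific < 0:
            specific, clamped = 0.0, True
        if irreversible < 0:
            irreversible, clamped = 0.0, True
        if irreversible > specific:
            # cannot retain more irreversibly than binds specifically
            irreversible, clamped = specific, True
        if clamped:
            warnings.warn(
                "negative or inconsistent binding component clamped",
                stacklevel=3,
            )
        object.__setattr__(self, "specific", specific)
        object.__setattr__(self, "irreversible", irreversible)
        object.__setattr__(self, "reversible", specific - irreversible)


def model_bound(kd: float, rt: float, ns: float, hot: float, conc) -> np.ndarray | float:
    """One-site homologous-competition bound signal at competitor conc(s).

    Strictly decreasing in ``conc`` when ``rt > 0``; tends to ``ns * hot`` as
    the competitor saturates the sites.
    """
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if hot < 0:
        raise ValueError("hot must be >= 0")
    conc_arr = np.asarray(conc, dtype=float)
    if (conc_arr < 0).any():
        raise ValueError("competitor concentrations must be >= 0")
    out = rt * hot / (kd + hot + conc_arr) + ns * hot
    return out if out.ndim else float(out)


def _initial_guess(curve: BindingCurve) -> tuple[float, float, float]:
    b = curve.bound
    h = curve.hot
    plateau = float(max(b.min(), 0.0))
    ns0 = plateau / h if h > 0 else 0.0
    span = float(max(b.max() - plateau, 1e-9))
    kd0 = float(np.median(curve.conc[curve.conc > 0])) if (curve.conc > 0).any() else 1.0
    kd0 = max(kd0, 1e-3)
    rt0 = span * (kd0 + h) / h
    return kd0, rt0, max(ns0, 0.0)


def fit_homologous_competition(
    curve: BindingCurve, weights: str = "proportional"
) -> BindingFit:
    """Weighted least-squares fit of (Kd, Rt, NS) to a competition curve.

    ``weights='proportional'`` applies 1/B^2 weighting (counting instruments
    show error proportional to the signal) via one reweighting pass with
    sigma taken from the first-pass fitted curve; ``weights='none'`` is
    ordinary least squares.  Standard errors are asymptotic, from the
    Jacobian at the solution.  Non-convergence and degenerate (flat) curves
    are flagged, never silently returned as good fits.
    """
    if curve.n_distinct() < 4:
        raise ValueError("need at least 4 distinct competitor concentrations")
    if weights not in ("proportional", "none"):
        raise ValueError(f"unknown weighting scheme {weights!r}")
    if np.ptp(curve.bound) == 0:
        return BindingFit(
            kd=np.nan, rt=np.nan, ns=np.nan,
            se_kd=np.nan, se_rt=np.nan, se_ns=np.nan,
            converged=False, degenerate=True,
        )

    def f(c, kd, rt, ns):
        return rt * curve.hot / (kd + curve.hot + c) + ns * curve.hot

    p0 = _initial_guess(curve)
    bounds = ([1e-9, 0.0, 0.0], [np.inf, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(
            f, curve.conc, curve.bound, p0=p0, bounds=bounds, maxfev=20_000
        )
        if weights == "proportional":
            sigma = np.maximum(f(curve.conc, *popt), 1e-12)
            popt, pcov = curve_fit(
                f, curve.conc, curve.bound, p0=popt, sigma=sigma,
                absolute_sigma=False, bounds=bounds, maxfev=20_000,
            )
    except RuntimeError:
        return BindingFit(
            kd=np.nan, rt=np.nan, ns=np.nan,
            se_kd=np.nan, se_rt=np.nan, se_ns=np.nan,
            converged=False,
        )
    se = np.sqrt(np.diag(pcov))
    return BindingFit(
        kd=float(popt[0]), rt=float(popt[1]), ns=float(popt[2]),
        se_kd=float(se[0]), se_rt=float(se[1]), se_ns=float(se[2]),
        converged=True,
    )


def dissect_binding(
    total: float, nonspecific: float, irreversible_sample: float
) -> DissectionResult:
    """Three-sample dissection of specific binding.

    specific = total - nonspecific; irreversible = irreversible_sample -
    nonspecific; reversible = specific - irreversible.  Negative components
    are clamped to zero (with a warning) in a way that preserves the
    conservation identity reversible + irreversible = specific.
    """
    return DissectionResult(
        total=total, nonspecific=nonspecific, irreversible_sample=irreversible_sample
    )


def simulate_binding_curve(
    kd: float,
    rt: float,
    ns: float,
    hot: float,
    conc,
    cv: float,
    n_rep: int,
    seed,
) -> list[BindingCurve]:
    """Simulate replicate competition curves with proportional Gaussian noise.

    Each bound value is ``model * (1 + eps)`` with ``eps ~ N(0, cv)``;
    ``cv=0`` reproduces the model exactly.  Deterministic for a fixed seed.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    conc_arr = np.asarray(conc, dtype=float)
    truth = model_bound(kd, rt, ns, hot, conc_arr)
    curves = []
    for _ in range(n_rep):
        eps = rng.normal(0.0, cv, size=conc_arr.shape) if cv > 0 else 0.0
        bound = np.maximum(truth * (1.0 + eps), 0.0)
        curves.append(BindingCurve(hot=hot, conc=conc_arr, bound=bound))
    return curves
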
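"""Monogenic recessive penetrance model for backcross resistance mapping.

Expected genotype distributions and mortalities for the crosses used in a
single-locus recessive-resistance design (resistant parental line, susceptible
parental line, F1 and first backcross to the resistant parent), plus an exact
binomial consistency test of observed bulk mortalities against the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import binomtest

__all__ = [
    "GENOTYPES",
    "PenetranceModel",
    "CrossOutcome",
    "MortalityTest",
    "genotype_distribution",
    "expected_mortality",
    "expected_background_fraction",
    "mortality_consistency",
]

#: Genotypes at the resistance locus: R = resistance allele, S = susceptible.
GENOTYPES = ("RR", "RS", "SS")

#: Recognized cross types.
CROSS_TYPES = ("F1", "BC1", "parental-R", "parental-S")


@dataclass(frozen=True)
class PenetranceModel:
    """Survival probability per genotype at the diagnostic insecticide dose.

    Defaults encode a completely recessive resistance with incomplete
    penetrance of the resistant homozygote: 35% of RR larvae survive while
    heterozygous and susceptible-homozygous larvae are all killed.
    """

    rr: float = 0.35
    rs: float = 0.0
    ss: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rr", "rs", "ss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"survival probability {name}={v} outside [0, 1]")

    def survival(self, genotype: str) -> float:
        """Survival probability of ``genotype`` ('RR' | 'RS' | 'SS')."""
        try:
            return {"RR": self.rr, "RS": self.rs, "SS": self.ss}[genotype]
        except KeyError:
            raise ValueError(f"unknown genotype {genotype!r}") from None

    @classmethod
    def neutral(cls) -> "PenetranceModel":
        """All genotypes survive: no selection."""
        return cls(rr=1.0, rs=1.0, ss=1.0)


@dataclass(frozen=True)
class CrossOutcome:
    """Genotype distribution at the locus and the implied expected mortality."""

    distribution: dict[str, float] = field(default_factory=dict)
    mortality: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"genotype distribution sums to {total}, not 1")
        if not 0.0 <= self.mortality <= 1.0:
            raise ValueError("mortality outside [0, 1]")


@dataclass(frozen=True)
class MortalityTest:
    """Exact binomial comparison of an observed mortality to an expectation."""

    observed: float
    expected: float
    p_value: float
    ci_low: float
    ci_high: float


def genotype_distribution(cross_type: str) -> dict[str, float]:
    """Mendelian genotype distribution at the resistance locus for a cross.

    The backcross is to the resistant parent, so BC1 segregates RR:RS = 1:1.
    """
    dists = {
        "F1": {"RS": 1.0},
        "BC1": {"RR": 0.5, "RS": 0.5},
        "parental-R": {"RR": 1.0},
        "parental-S": {"SS": 1.0},
    }
    try:
        return dict(dists[cross_type])
    except KeyError:
        raise ValueError(
            f"unknown cross type {cross_type!r}; expected one of {CROSS_TYPES}"
        ) from None


def expected_mortality(
    distribution: dict[str, float], penetrance: PenetranceModel
) -> float:
    """Expected mortality ``1 - sum_g P(g) * survival(g)`` for a cross."""
    total = sum(distribution.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"genotype distribution sums to {total}, not 1")
    survive = sum(p * penetrance.survival(g) for g, p in distribution.items())
    return 1.0 - survive


def cross_outcome(cross_type: str, penetrance: PenetranceModel) -> CrossOutcome:
    """Bundle the genotype distribution and expected mortality for a cross."""
    dist = genotype_distribution(cross_type)
    return CrossOutcome(distribution=dist, mortality=expected_mortality(dist, penetrance))


def expected_background_fraction(cross_type: str) -> float:
    """Expected resistant-parent allele dosage at loci unlinked to selection.

    For a BC1 to the resistant parent every offspring carries one full
    resistant haplotype plus an F1 gamete that is resistant with probability
    1/2, giving (1 + 0.5) / 2 = 0.75 genome-wide.  An F1 carries one haplotype
    from each parent: 0.5.
    """
    if cross_type == "BC1":
        return 0.75
    if cross_type == "F1":
        return 0.5
    raise ValueError(f"unsupported cross type {cross_type!r} (expected BC1 or F1)")


def mortality_consistency(dead: int, n: int, expected: float) -> MortalityTest:
    """Two-sided exact binomial test of an observed mortality count.

    Returns the p-value of ``dead`` successes out of ``n`` against the
    expected mortality fraction, plus the Clopper-Pearson 95% confidence
    interval of the observed proportion.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= dead <= n:
        raise ValueError(f"dead={dead} outside [0, {n}]")
    if not 0.0 <= expected <= 1.0:
        raise ValueError("expected mortality outside [0, 1]")
    result = binomtest(dead, n, expected, alternative="two-sided")
    ci = result.proportion_ci(confidence_level=0.95, method="exact")
    return MortalityTest(
        observed=dead / n,
        expected=expected,
        p_value=result.pvalue,
        ci_low=ci.low,
        ci_high=ci.high,
    )
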
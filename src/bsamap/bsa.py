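"""Asymmetric single-bulk segregant scan over ortholog-anchored unigenes.

The per-unigene fixation index is the ratio of informative SNPs whose
resistant-parent allele is fixed in the selected bulk (frequency strictly
above the fixation threshold) to the total number of informative SNPs in the
unigene.  Unigenes are placed on a reference genome through reciprocal-best-
hit orthologs, indexes are smoothed with overlapping rolling windows of
consecutive anchored unigenes, and runs of window means strictly above the
region threshold are merged into candidate regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variants import InformativeSNP

__all__ = [
    "UnigeneIndex",
    "Window",
    "Region",
    "ScanResult",
    "bsa_index",
    "reciprocal_best_hits",
    "anchor_unigenes",
    "rolling_windows",
    "call_regions",
    "scan",
    "plot_scan",
]

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]


@dataclass(frozen=True)
class UnigeneIndex:
    """Fixation index of one unigene: n_fixed / n_snps over informative SNPs."""

    unigene: str
    n_snps: int
    n_fixed: int
    index: float  # NaN when undefined (n_snps below the configured minimum)

    @property
    def defined(self) -> bool:
        return not math.isnan(self.index)


@dataclass(frozen=True)
class Window:
    """Mean index over ``window_size`` consecutive anchored unigenes."""

    chrom: str
    start_rank: int
    unigenes: tuple[str, ...]
    span: tuple[int, int]
    mean_index: float


@dataclass(frozen=True)
class Region:
    """A maximal run of above-threshold windows merged into one genomic span."""

    chrom: str
    start: int
    end: int
    unigenes: tuple[str, ...]
    peak_mean: float

    @property
    def n_unigenes(self) -> int:
        return len(self.unigenes)


@dataclass
class ScanResult:
    """Tables produced by one end-to-end scan."""

    indexes: pd.DataFrame
    anchors: pd.DataFrame
    windows: pd.DataFrame
    regions: pd.DataFrame
    params: dict = field(default_factory=dict)

    def top_region(self) -> Region | None:
        """Highest-peak region (ties: more unigenes, then genomic order)."""
        if self.regions.empty:
            return None
        df = self.regions.sort_values(
            ["peak_mean", "n_unigenes", "chrom", "start"],
            ascending=[False, False, True, True],
        )
        row = df.iloc[0]
        return Region(
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            unigenes=tuple(row["unigenes"].split(",")),
            peak_mean=float(row["peak_mean"]),
        )


def bsa_index(snps: list[InformativeSNP], min_snps: int = 1) -> UnigeneIndex:
    """Per-unigene fixation index from its informative SNPs.

    SNPs whose bulk frequency is undefined (low coverage) do not contribute.
    The index is NaN when fewer than ``min_snps`` SNPs remain.
    """
    unigenes = {s.unigene for s in snps}
    if len(unigenes) > 1:
        raise ValueError(f"SNPs from multiple unigenes: {sorted(unigenes)}")
    usable = [s for s in snps if s.fixed is not None]
    n_snps = len(usable)
    n_fixed = sum(1 for s in usable if s.fixed)
    index = n_fixed / n_snps if n_snps >= max(min_snps, 1) else math.nan
    unigene = next(iter(unigenes)) if unigenes else ""
    return UnigeneIndex(unigene=unigene, n_snps=n_snps, n_fixed=n_fixed, index=index)


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per query: the best hit by bitscore, then e-value, then id."""
    missing = [c for c in ("qseqid", "sseqid", "bitscore", "evalue") if c not in hits.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    ordered = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.groupby("qseqid", as_index=False).first()


def reciprocal_best_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal best hits between unigenes (A) and reference genes (B).

    Returns a DataFrame with columns ``unigene`` and ``gene`` containing the
    pairs (u, g) where g is u's best hit in A->B and u is g's best hit in
    B->A.  Ties are broken by bitscore (desc), e-value (asc) and subject id
    (asc), so the output is deterministic.
    """
    if hits_ab.empty or hits_ba.empty:
        return pd.DataFrame(columns=["unigene", "gene"])
    best_ab = _best_hits(hits_ab)[["qseqid", "sseqid"]]
    best_ba = _best_hits(hits_ba)[["qseqid", "sseqid"]]
    merged = best_ab.merge(
        best_ba,
        left_on=["qseqid", "sseqid"],
        right_on=["sseqid", "qseqid"],
        suffixes=("_ab", "_ba"),
    )
    out = merged[["qseqid_ab", "sseqid_ab"]].rename(
        columns={"qseqid_ab": "unigene", "sseqid_ab": "gene"}
    )
    return out.sort_values("unigene", kind="mergesort").reset_index(drop=True)


def anchor_unigenes(pairs: pd.DataFrame, gene_positions: pd.DataFrame) -> pd.DataFrame:
    """Place RBH-paired unigenes at their reference gene coordinates.

    ``gene_positions`` needs columns gene, chrom, start, end.  Returns
    anchors sorted by (chrom, start) with a per-chromosome ``rank`` column
    (1-based, consecutive).  Pairs whose gene has no position record are
    excluded with a warning.
    """
    required = {"gene", "chrom", "start", "end"}
    missing = required - set(gene_positions.columns)
    if missing:
        raise ValueError(f"gene position table missing columns: {sorted(missing)}")
    merged = pairs.merge(gene_positions, on="gene", how="left", validate="one_to_one")
    lost = merged[merged["chrom"].isna()]
    if not lost.empty:
        warnings.warn(
            f"{len(lost)} RBH pair(s) excluded: gene absent from position table "
            f"({', '.join(lost['gene'].head(5))}{'...' if len(lost) > 5 else ''})"
        )
        merged = merged.dropna(subset=["chrom"])
    anchors = merged.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    anchors["start"] = anchors["start"].astype(int)
    anchors["end"] = anchors["end"].astype(int)
    anchors["rank"] = anchors.groupby("chrom").cumcount() + 1
    return anchors[["unigene", "gene", "chrom", "start", "end", "rank"]]


def rolling_windows(
    anchored: pd.DataFrame, window_size: int = 3
) -> list[Window]:
    """Overlapping rolling windows of consecutive anchored unigene indexes.

    ``anchored`` must carry columns chrom, start, end, rank, unigene, index.
    Unigenes with an undefined (NaN) index are excluded before windowing —
    absence of SNP evidence is not evidence against fixation — and ranks are
    re-derived over the remaining anchors.  One window per run of
    ``window_size`` consecutive anchors, stride 1; chromosomes with fewer
    anchors yield none.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    usable = anchored.dropna(subset=["index"])
    windows: list[Window] = []
    for chrom, grp in usable.groupby("chrom", sort=True):
        grp = grp.sort_values("start", kind="mergesort").reset_index(drop=True)
        n = len(grp)
        if n < window_size:
            continue
        idx = grp["index"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        names = grp["unigene"].to_numpy()
        for i in range(n - window_size + 1):
            j = i + window_size
            windows.append(
                Window(
                    chrom=chrom,
                    start_rank=i + 1,
                    unigenes=tuple(names[i:j]),
                    span=(int(starts[i:j].min()), int(ends[i:j].max())),
                    mean_index=float(idx[i:j].mean()),
                )
            )
    return windows


def call_regions(windows: list[Window], threshold: float = 0.60) -> list[Region]:
    """Merge maximal runs of consecutive above-threshold windows into regions.

    A window participates iff its mean index is strictly greater than
    ``threshold``.  Consecutive means adjacent start ranks on the same
    chromosome.  The region span is the min start / max end over member
    anchors; the unigene list is the distinct members in genomic order.
    """
    regions: list[Region] = []
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: w.start_rank)
        run: list[Window] = []
        for w in ws + [None]:  # type: ignore[list-item]
            extend = (
                w is not None
                and w.mean_index > threshold
                and (not run or w.start_rank == run[-1].start_rank + 1)
            )
            if extend:
                run.append(w)
                continue
            if run:
                members: list[str] = []
                for rw in run:
                    for u in rw.unigenes:
                        if u not in members:
                            members.append(u)
                regions.append(
                    Region(
                        chrom=chrom,
                        start=min(rw.span[0] for rw in run),
                        end=max(rw.span[1] for rw in run),
                        unigenes=tuple(members),
                        peak_mean=max(rw.mean_index for rw in run),
                    )
                )
                run = []
            if w is not None and w.mean_index > threshold:
                run = [w]
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


# ---------------------------------------------------------------------------
# driver


def _index_table(indexes: list[UnigeneIndex]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unigene": [u.unigene for u in indexes],
            "n_snps": [u.n_snps for u in indexes],
            "n_fixed": [u.n_fixed for u in indexes],
            "index": [u.index for u in indexes],
        }
    )


def _window_table(windows: list[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start_rank": [w.start_rank for w in windows],
            "start": [w.span[0] for w in windows],
            "end": [w.span[1] for w in windows],
            "unigenes": [",".join(w.unigenes) for w in windows],
            "mean_index": [w.mean_index for w in windows],
        }
    )


def _region_table(regions: list[Region]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "n_unigenes": [r.n_unigenes for r in regions],
            "unigenes": [",".join(r.unigenes) for r in regions],
            "peak_mean": [r.peak_mean for r in regions],
        }
    )


def scan(
    snps: list[InformativeSNP],
    hits_fwd: pd.DataFrame,
    hits_rev: pd.DataFrame,
    gene_positions: pd.DataFrame,
    window_size: int = 3,
    region_threshold: float = 0.60,
    min_snps: int = 1,
) -> ScanResult:
    """End-to-end scan: index -> anchor -> window -> region tables.

    Deterministic: identical inputs give identical outputs.  Component
    errors propagate with a stage label prefixed to the message.
    """
    params = {
        "window_size": window_size,
        "region_threshold": region_threshold,
        "min_snps": min_snps,
    }

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"scan stage '{name}' failed: {exc}") from exc

    by_unigene: dict[str, list[InformativeSNP]] = {}
    for s in snps:
        by_unigene.setdefault(s.unigene, []).append(s)
    indexes = [
        stage("index", bsa_index, grp, min_snps) for grp in by_unigene.values()
    ]
    index_df = _index_table(indexes)

    pairs = stage("rbh", reciprocal_best_hits, hits_fwd, hits_rev)
    anchors = stage("anchor", anchor_unigenes, pairs, gene_positions)
    anchored = anchors.merge(index_df[["unigene", "index"]], on="unigene", how="left")
    windows = stage("windows", rolling_windows, anchored, window_size)
    regions = stage("regions", call_regions, windows, region_threshold)
    return ScanResult(
        indexes=index_df,
        anchors=anchored,
        windows=_window_table(windows),
        regions=_region_table(regions),
        params=params,
    )


def plot_scan(result: ScanResult, path: str) -> None:
    """Manhattan-style plot of window mean index along the reference genome.

    Windows above the region threshold are drawn in red, per-chromosome
    panels share the y-axis [0, 1].
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    windows = result.windows
    threshold = result.params.get("region_threshold", 0.60)
    chroms = sorted(windows["chrom"].unique()) if not windows.empty else []
    n = max(len(chroms), 1)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), sharey=True, squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        sub = windows[windows["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        above = sub["mean_index"] > threshold
        ax.scatter(mid[~above], sub.loc[~above, "mean_index"], s=8, color="0.4")
        ax.scatter(mid[above], sub.loc[above, "mean_index"], s=10, color="crimson")
        ax.axhline(threshold, ls="--", lw=0.8, color="0.6")
        ax.set_title(str(chrom), fontsize=9)
        ax.set_xlabel("Mb")
        ax.set_ylim(-0.05, 1.05)
    axes[0][0].set_ylabel("mean fixation index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
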
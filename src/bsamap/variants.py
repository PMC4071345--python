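"""Per-SNP allele counts: parsing, informative-SNP calling, deletion detection.

Variant tables carry per-sample ref/alt read counts for three samples — the
resistant parent, the susceptible parent and the selected bulk — keyed by the
canonical sample names in :data:`SAMPLES`.  Two input dialects are supported:
a long-format TSV and a minimal VCF v4.2 with per-sample allele depths (AD).

Coordinates are 1-based inclusive in transcript (unigene) space throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "SAMPLES",
    "VariantRecord",
    "InformativeSNP",
    "DeletionCall",
    "read_variant_table",
    "records_from_frame",
    "call_informative",
    "is_fixed",
    "deletion_scan",
    "deletion_protein_effect",
]

#: Canonical sample keys, in table order.
SAMPLES = ("res_parent", "sus_parent", "bulk")

#: Long-format TSV column schema.
TSV_COLUMNS = ["unigene", "pos", "ref", "alt", "sample", "ref_count", "alt_count"]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNP with per-sample (ref_count, alt_count)."""

    unigene: str
    pos: int
    ref: str
    alt: str
    counts: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("position must be >= 1 (1-based)")
        for sample, (r, a) in self.counts.items():
            if r < 0 or a < 0:
                raise ValueError(f"negative count for sample {sample!r}")

    def coverage(self, sample: str) -> int:
        r, a = self.counts[sample]
        return r + a


@dataclass(frozen=True)
class InformativeSNP:
    """A variant whose parents carry opposite alleles, with bulk frequency.

    ``res_allele`` records which allele ('ref' or 'alt') the resistant parent
    carries; ``bulk_freq`` is the frequency of that allele in the selected
    bulk, NaN when bulk coverage is below the configured minimum.  ``fixed``
    is None when the frequency is undefined.
    """

    record: VariantRecord
    res_allele: str
    bulk_freq: float
    fixed: bool | None

    @property
    def unigene(self) -> str:
        return self.record.unigene

    @property
    def pos(self) -> int:
        return self.record.pos


@dataclass(frozen=True)
class DeletionCall:
    """A zero-coverage interval in the resistant track, 1-based inclusive."""

    start: int
    end: int
    sus_mean_cov: float
    res_max_cov: int
    unigene: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# parsing


def _read_tsv(path: Path, sample_map: dict[str, str]) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"unigene": str})
    if df.empty:
        return []
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    rev = {v: k for k, v in sample_map.items()}
    unknown = set(df["sample"]) - set(rev)
    if unknown:
        raise ValueError(f"{path}: unmapped sample names {sorted(unknown)}")
    records: list[VariantRecord] = []
    grouped = df.groupby(["unigene", "pos", "ref", "alt"], sort=False)
    for (unigene, pos, ref, alt), grp in grouped:
        counts: dict[str, tuple[int, int]] = {}
        for row in grp.itertuples():
            counts[rev[row.sample]] = (int(row.ref_count), int(row.alt_count))
        absent = [s for s in SAMPLES if s not in counts]
        if absent:
            raise ValueError(
                f"{path}: variant {unigene}:{pos} missing samples {absent}"
            )
        records.append(
            VariantRecord(unigene=str(unigene), pos=int(pos), ref=ref, alt=alt, counts=counts)
        )
    return records


def _read_vcf(path: Path, sample_map: dict[str, str]) -> list[VariantRecord]:
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        absent = [v for v in sample_map.values() if v not in header_samples]
        if absent:
            raise ValueError(f"{path}: VCF lacks sample columns {absent}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                warnings.warn(
                    f"{path}: dropping non-biallelic record {rec.chrom}:{rec.pos}"
                )
                continue
            counts: dict[str, tuple[int, int]] = {}
            for canon, name in sample_map.items():
                ad = rec.samples[name].get("AD")
                if ad is None or len(ad) < 2:
                    raise ValueError(
                        f"{path}: missing AD for sample {name} at {rec.chrom}:{rec.pos}"
                    )
                counts[canon] = (int(ad[0]), int(ad[1]))
            records.append(
                VariantRecord(
                    unigene=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    counts=counts,
                )
            )
    return records


def read_variant_table(
    path: str | Path,
    dialect: str = "tsv",
    sample_map: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Read a variant table in TSV or VCF dialect into VariantRecords.

    ``sample_map`` maps canonical keys ('res_parent', 'sus_parent', 'bulk')
    to the sample names used in the file; by default the canonical names are
    expected verbatim.  Multiallelic VCF records are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sample_map = sample_map or {s: s for s in SAMPLES}
    if set(sample_map) != set(SAMPLES):
        raise ValueError(f"sample_map keys must be exactly {SAMPLES}")
    if dialect == "tsv":
        if path.stat().st_size == 0:
            return []
        return _read_tsv(path, sample_map)
    if dialect == "vcf":
        return _read_vcf(path, sample_map)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'vcf')")


def records_from_frame(
    df: pd.DataFrame, sample_map: dict[str, str] | None = None
) -> list[VariantRecord]:
    """Build VariantRecords from an in-memory long-format count table."""
    sample_map = sample_map or {s: s for s in SAMPLES}
    rev = {v: k for k, v in sample_map.items()}
    records = []
    for key, grp in df.groupby(["unigene", "pos", "ref", "alt"], sort=False):
        unigene, pos, ref, alt = key
        counts = {
            rev[row.sample]: (int(row.ref_count), int(row.alt_count))
            for row in grp.itertuples()
        }
        records.append(
            VariantRecord(unigene=str(unigene), pos=int(pos), ref=ref, alt=alt, counts=counts)
        )
    return records


# ---------------------------------------------------------------------------
# informative-SNP calling


def call_informative(
    record: VariantRecord,
    min_parent_cov: int = 10,
    parent_purity: float = 0.9,
    min_bulk_cov: int = 20,
    fix_threshold: float = 0.95,
) -> InformativeSNP | None:
    """Classify a variant as informative and compute the bulk frequency.

    A variant is informative when both parents are covered at
    ``min_parent_cov`` or more and carry *opposite* alleles, each at
    frequency >= ``parent_purity`` within its own sample.  The resistant
    parent's allele is recorded and the frequency of that allele in the bulk
    is reported (NaN, with ``fixed=None``, when bulk coverage is below
    ``min_bulk_cov``).  Returns None for uninformative variants.
    """
    res_r, res_a = record.counts["res_parent"]
    sus_r, sus_a = record.counts["sus_parent"]
    res_cov, sus_cov = res_r + res_a, sus_r + sus_a
    if res_cov < min_parent_cov or sus_cov < min_parent_cov:
        return None

    def major(r: int, a: int) -> tuple[str, float]:
        cov = r + a
        return ("ref", r / cov) if r >= a else ("alt", a / cov)

    res_allele, res_frac = major(res_r, res_a)
    sus_allele, sus_frac = major(sus_r, sus_a)
    if res_frac < parent_purity or sus_frac < parent_purity:
        return None
    if res_allele == sus_allele:
        return None

    bulk_r, bulk_a = record.counts["bulk"]
    bulk_cov = bulk_r + bulk_a
    if bulk_cov < min_bulk_cov:
        return InformativeSNP(
            record=record, res_allele=res_allele, bulk_freq=math.nan, fixed=None
        )
    res_reads = bulk_r if res_allele == "ref" else bulk_a
    freq = res_reads / bulk_cov
    return InformativeSNP(
        record=record,
        res_allele=res_allele,
        bulk_freq=freq,
        fixed=is_fixed(freq, fix_threshold),
    )


def is_fixed(frequency: float, threshold: float = 0.95) -> bool:
    """Strictly-greater-than fixation test of a bulk allele frequency."""
    if not 0.0 <= frequency <= 1.0:
        raise ValueError(f"frequency {frequency} outside [0, 1]")
    return frequency > threshold


# ---------------------------------------------------------------------------
# deletion footprint


def deletion_scan(
    res_track,
    sus_track,
    min_len: int = 50,
    min_sus_cov: float = 10.0,
    max_res_cov: int = 0,
    unigene: str | None = None,
) -> list[DeletionCall]:
    """Find deletion footprints: resistant coverage absent, susceptible present.

    Returns maximal intervals of length >= ``min_len`` where the resistant
    track never exceeds ``max_res_cov`` and the susceptible track's mean
    coverage over the interval is >= ``min_sus_cov``.  Intervals are 1-based
    inclusive, non-overlapping and sorted.
    """
    res = np.asarray(res_track)
    sus = np.asarray(sus_track)
    if res.shape != sus.shape or res.ndim != 1:
        raise ValueError("coverage tracks must be 1-D and of equal length")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    ok = res <= max_res_cov
    if not ok.any():
        return []
    padded = np.concatenate(([False], ok, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)   # 0-based run starts
    ends = np.flatnonzero(edges == -1)    # 0-based run ends (exclusive)
    calls = []
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        sus_mean = float(sus[s:e].mean())
        if sus_mean < min_sus_cov:
            continue
        calls.append(
            DeletionCall(
                start=int(s + 1),
                end=int(e),
                sus_mean_cov=sus_mean,
                res_max_cov=int(res[s:e].max()),
                unigene=unigene,
            )
        )
    return calls


def deletion_protein_effect(
    cds_interval: tuple[int, int], deletion_interval: tuple[int, int]
) -> dict:
    """Protein-level arithmetic of a deletion overlapping a CDS.

    Both intervals are 1-based inclusive in transcript coordinates.  The
    deletion is in frame iff its overlap with the CDS has length divisible
    by 3; then ``aa_removed`` = overlap / 3.  An in-frame deletion that is
    not aligned to codon boundaries fuses two partial codons and may create
    a premature stop, as may any frameshift.  A deletion entirely in the UTR
    yields the zero-effect result.
    """
    cds_start, cds_end = cds_interval
    del_start, del_end = deletion_interval
    if cds_start < 1 or cds_end < cds_start:
        raise ValueError("malformed CDS interval")
    if del_start < 1 or del_end < del_start:
        raise ValueError("malformed deletion interval")
    ov_start = max(cds_start, del_start)
    ov_end = min(cds_end, del_end)
    overlap = max(0, ov_end - ov_start + 1)
    if overlap == 0:
        return {"in_frame": True, "aa_removed": 0, "premature_stop_possible": False}
    in_frame = overlap % 3 == 0
    codon_aligned = (ov_start - cds_start) % 3 == 0
    return {
        "in_frame": in_frame,
        "aa_removed": overlap // 3 if in_frame else 0,
        "premature_stop_possible": (not in_frame) or (not codon_aligned),
    }
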
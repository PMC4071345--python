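"""Transcriptome bookkeeping: RPKM, unigene filtering, cluster representatives.

Annotation tables are pandas DataFrames with columns ``unigene``, ``cluster``,
``length``, ``has_cds``, ``has_homolog`` and ``read_count``.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ANNOTATION_COLUMNS",
    "rpkm",
    "filter_unigenes",
    "cluster_representative",
]

ANNOTATION_COLUMNS = ["unigene", "cluster", "length", "has_cds", "has_homolog", "read_count"]


def rpkm(read_count: int | float, length: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    return read_count / (length / 1_000.0) / (total_mapped / 1e6)


def _validate(annotations: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if (annotations["length"] < 1).any():
        raise ValueError("unigene lengths must be >= 1")
    if (annotations["read_count"] < 0).any():
        raise ValueError("read counts must be >= 0")


def filter_unigenes(
    annotations: pd.DataFrame,
    total_mapped: int,
    rpkm_min: float = 0.25,
    len_min: int = 500,
) -> pd.DataFrame:
    """Keep unigenes passing any one of four disjunctive criteria.

    A unigene is retained iff it has a CDS, OR has a homology match, OR is
    expressed above ``rpkm_min`` RPKM (strict), OR is longer than ``len_min``
    bp (strict).  ``total_mapped`` is the library's total mapped-read count
    used to compute RPKM.  Returns the kept rows with an ``rpkm`` column
    added; input order is preserved.
    """
    _validate(annotations)
    out = annotations.copy()
    out["rpkm"] = [
        rpkm(rc, ln, total_mapped)
        for rc, ln in zip(out["read_count"], out["length"])
    ]
    keep = (
        out["has_cds"].astype(bool)
        | out["has_homolog"].astype(bool)
        | (out["rpkm"] > rpkm_min)
        | (out["length"] > len_min)
    )
    return out[keep].reset_index(drop=True)


def cluster_representative(annotations: pd.DataFrame) -> pd.DataFrame:
    """Pick one representative unigene per cluster: the longest member.

    Length ties are broken by the lexicographically smallest unigene id so
    the choice is deterministic.  Returns one row per cluster, sorted by
    cluster id.
    """
    _validate(annotations)
    ordered = annotations.sort_values(
        ["cluster", "length", "unigene"], ascending=[True, False, True]
    )
    return ordered.groupby("cluster", as_index=False).first()
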
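"""Readers and writers for the plain-text interchange formats.

All TSV outputs start with ``#``-prefixed header comments recording the
generating parameters, so every file is self-describing and reruns are
diffable.  Readers skip those comments.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import BulkCounts

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_counts_tsv",
    "write_counts_vcf",
    "write_hits",
    "read_hits",
    "write_gene_table",
    "read_gene_table",
    "write_track",
    "read_track",
]

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]
GENE_COLUMNS = ["gene", "chrom", "start", "end", "strand"]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def write_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a DataFrame as TSV with optional ``# key=value`` header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def counts_table(counts: BulkCounts) -> pd.DataFrame:
    """Long-format variant table view of simulated counts.

    The susceptible-parent allele is REF ('A') and the resistant allele ALT
    ('G'), so ref_count = susceptible reads and alt_count = resistant reads.
    """
    df = counts.frame
    return pd.DataFrame(
        {
            "unigene": df["unigene"],
            "pos": df["upos"],
            "ref": "A",
            "alt": "G",
            "sample": df["sample"],
            "ref_count": df["sus_count"],
            "alt_count": df["res_count"],
        }
    )


def write_counts_tsv(counts: BulkCounts, path: str | Path, meta: dict | None = None) -> None:
    """Allele-count TSV: unigene pos ref alt sample ref_count alt_count."""
    write_tsv(counts_table(counts), path, meta)


def write_counts_vcf(counts: BulkCounts, path: str | Path, meta: dict | None = None) -> None:
    """Minimal VCF v4.2 with per-sample allele depths (AD), one line per SNP.

    CHROM is the unigene id and POS the 1-based transcript position; the
    allele convention matches :func:`write_counts_tsv`.
    """
    df = counts.frame
    samples = list(dict.fromkeys(df["sample"]))
    wide = df.pivot_table(
        index=["unigene", "upos"],
        columns="sample",
        values=["sus_count", "res_count"],
        aggfunc="first",
        sort=False,
    )
    with open(Path(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for k, v in (meta or {}).items():
            fh.write(f"##{k}={v}\n")
        for unigene in dict.fromkeys(df["unigene"]):
            length = int(df.loc[df["unigene"] == unigene, "upos"].max()) + 1000
            fh.write(f"##contig=<ID={unigene},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for (unigene, upos), row in wide.iterrows():
            fields = [unigene, str(int(upos)), ".", "A", "G", ".", "PASS", ".", "AD"]
            for s in samples:
                ref_c = int(row[("sus_count", s)])
                alt_c = int(row[("res_count", s)])
                fields.append(f"{ref_c},{alt_c}")
            fh.write("\t".join(fields) + "\n")


def write_hits(hits: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """BLAST-tabular-like hit file (qseqid sseqid pident length evalue bitscore)."""
    write_tsv(hits[HIT_COLUMNS], path, meta)


def read_hits(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: hit table missing columns {missing}")
    return df


def write_gene_table(genes: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    write_tsv(genes[GENE_COLUMNS], path, meta)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = [c for c in GENE_COLUMNS if c not in df.columns and c != "strand"]
    if missing:
        raise ValueError(f"{path}: gene table missing columns {missing}")
    return df


def write_track(track: np.ndarray, path: str | Path, meta: dict | None = None) -> None:
    """Per-base coverage as two-column TSV (pos, depth), 1-based."""
    df = pd.DataFrame({"pos": np.arange(1, len(track) + 1), "depth": track})
    write_tsv(df, path, meta)


def read_track(path: str | Path) -> np.ndarray:
    df = read_tsv(path)
    if not {"pos", "depth"} <= set(df.columns):
        raise ValueError(f"{path}: coverage track needs 'pos' and 'depth' columns")
    order = np.argsort(df["pos"].to_numpy())
    return df["depth"].to_numpy()[order]
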
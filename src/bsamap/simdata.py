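"""Synthetic backcross populations and pooled allele-count tables.

Generates everything the downstream scan consumes without any real data:
a genome map of SNP markers grouped into unigenes, BC1 offspring produced by
Haldane (no-interference) meiosis of an F1 gamete onto a full resistant
haplotype, survival selection at a recessive locus, pooled read counts with
negative-binomial coverage and optional allele-specific-expression bias,
zero-coverage deletion footprints, and directional homology hit tables from
which reciprocal best hits recover the true unigene-to-gene map.

Genotypes are encoded as the resistant-allele dosage of the offspring:
``RR = 2`` (gamete carried R) and ``RS = 1`` (gamete carried S); the
recurrent resistant parent always contributes one R haplotype.

All randomness flows from an explicit seed through ``numpy.random.default_rng``;
no global state is touched, and equal seeds give bitwise-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import PenetranceModel

__all__ = [
    "RR",
    "RS",
    "Chromosome",
    "Marker",
    "GenomeMap",
    "CrossDesign",
    "BulkCounts",
    "build_genome_map",
    "simulate_backcross",
    "apply_selection",
    "simulate_bulk_counts",
    "simulate_parent_counts",
    "simulate_coverage_tracks",
    "inject_deletion",
    "generate_hit_tables",
    "reference_gene_table",
    "simulate_experiment",
    "Experiment",
]

RR = 2  #: homozygous resistant (gamete allele R)
RS = 1  #: heterozygous (gamete allele S)


@dataclass(frozen=True)
class Chromosome:
    name: str
    genetic_length: float  # Morgans
    physical_length: int   # bp


@dataclass(frozen=True)
class Marker:
    """One SNP marker: a member of a unigene placed on the genome map."""

    id: str
    unigene: str
    chrom: str
    gpos: float  # genetic position, Morgans
    ppos: int    # physical position, bp
    upos: int    # 1-based position within the unigene's transcript


@dataclass(frozen=True)
class GenomeMap:
    chromosomes: tuple[Chromosome, ...]
    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        lengths = {c.name: c for c in self.chromosomes}
        last_ppos: dict[str, int] = {}
        unigene_chrom: dict[str, str] = {}
        for m in self.markers:
            c = lengths.get(m.chrom)
            if c is None:
                raise ValueError(f"marker {m.id} on unknown chromosome {m.chrom}")
            if not 0.0 <= m.gpos <= c.genetic_length:
                raise ValueError(f"marker {m.id} genetic position off the map")
            if m.chrom in last_ppos and m.ppos <= last_ppos[m.chrom]:
                raise ValueError(f"physical positions not strictly increasing at {m.id}")
            last_ppos[m.chrom] = m.ppos
            prev = unigene_chrom.setdefault(m.unigene, m.chrom)
            if prev != m.chrom:
                raise ValueError(f"unigene {m.unigene} spans chromosomes")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [m.id for m in self.markers],
                "unigene": [m.unigene for m in self.markers],
                "chrom": [m.chrom for m in self.markers],
                "gpos": [m.gpos for m in self.markers],
                "ppos": [m.ppos for m in self.markers],
                "upos": [m.upos for m in self.markers],
            }
        )

    def chrom(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def nearest_marker(self, chrom: str, gpos: float) -> int:
        """Index of the marker nearest a genetic position on a chromosome.

        Ties go to the lower physical coordinate.
        """
        best, best_key = None, None
        for i, m in enumerate(self.markers):
            if m.chrom != chrom:
                continue
            key = (abs(m.gpos - gpos), m.ppos)
            if best_key is None or key < best_key:
                best, best_key = i, key
        if best is None:
            raise ValueError(f"no markers on chromosome {chrom!r}")
        return best

    def unigenes(self) -> list[str]:
        seen: list[str] = []
        for m in self.markers:
            if m.unigene not in seen:
                seen.append(m.unigene)
        return seen


@dataclass(frozen=True)
class CrossDesign:
    """Cross type, resistance-locus position and per-genotype penetrance."""

    cross_type: str = "BC1"
    locus_chrom: str = "chr1"
    locus_gpos: float = 0.5
    penetrance: PenetranceModel = field(default_factory=PenetranceModel)

    def __post_init__(self) -> None:
        if self.cross_type not in ("F1", "BC1"):
            raise ValueError(f"unsupported cross type {self.cross_type!r}")


@dataclass(frozen=True)
class BulkCounts:
    """Long-format per-marker, per-sample resistant/susceptible read counts."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "unigene", "chrom", "upos", "sample", "res_count", "sus_count"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"BulkCounts frame missing columns: {sorted(missing)}")
        if (self.frame[["res_count", "sus_count"]] < 0).any().any():
            raise ValueError("negative read counts")

    def coverage(self) -> pd.Series:
        return self.frame["res_count"] + self.frame["sus_count"]


# ---------------------------------------------------------------------------
# map construction


def build_genome_map(
    n_chrom: int,
    unigenes_per_chrom: int,
    snps_per_unigene: int,
    genetic_len: float = 1.0,
    physical_len: int = 3_000_000,
    seed: int | np.random.SeedSequence = 0,
) -> GenomeMap:
    """Build a genome map of SNP markers grouped into unigenes.

    Unigene centres are evenly spaced along each chromosome with a small
    seeded jitter in genetic position; a unigene's SNPs share its genetic
    position (intragenic recombination is negligible) and occupy consecutive
    physical/transcript offsets.  Markers come out sorted by physical
    position within each chromosome.
    """
    if min(n_chrom, unigenes_per_chrom, snps_per_unigene) < 1:
        raise ValueError("all counts must be >= 1")
    if genetic_len < 0 or physical_len <= 0:
        raise ValueError("lengths must be positive (genetic length may be 0)")
    rng = np.random.default_rng(seed)
    chromosomes = []
    markers = []
    spacing_g = genetic_len / unigenes_per_chrom
    spacing_p = physical_len / unigenes_per_chrom
    for c in range(1, n_chrom + 1):
        cname = f"chr{c}"
        chromosomes.append(Chromosome(cname, genetic_len, int(physical_len)))
        jitter = rng.uniform(-0.2, 0.2, size=unigenes_per_chrom) * spacing_g
        gcenters = np.sort(
            np.clip((np.arange(unigenes_per_chrom) + 0.5) * spacing_g + jitter, 0.0, genetic_len)
        )
        for i in range(unigenes_per_chrom):
            uname = f"UG{c:02d}_{i + 1:03d}"
            pstart = int(round((i + 0.25) * spacing_p))
            for j in range(snps_per_unigene):
                markers.append(
                    Marker(
                        id=f"{uname}:snp{j + 1}",
                        unigene=uname,
                        chrom=cname,
                        gpos=float(gcenters[i]),
                        ppos=pstart + j * 10,
                        upos=101 + j * 10,
                    )
                )
    return GenomeMap(chromosomes=tuple(chromosomes), markers=tuple(markers))


# ---------------------------------------------------------------------------
# meiosis and selection


def _gamete_alleles(
    gpos: np.ndarray, genetic_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one F1 gamete: True where the gamete carries the R allele.

    Crossovers per chromosome ~ Poisson(genetic length in Morgans),
    breakpoints uniform, no interference (Haldane).
    """
    n_xo = rng.poisson(genetic_length) if genetic_length > 0 else 0
    phase0 = rng.integers(0, 2)
    if n_xo == 0:
        return np.full(gpos.shape, phase0 == 0)
    cuts = np.sort(rng.uniform(0.0, genetic_length, size=n_xo))
    phase = (phase0 + np.searchsorted(cuts, gpos, side="right")) % 2
    return phase == 0


def simulate_backcross(
    gmap: GenomeMap,
    design: CrossDesign,
    n_offspring: int,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Simulate BC1 offspring genotypes at every marker.

    Each offspring is one full resistant haplotype (from the recurrent
    parent) plus one recombinant F1 gamete, so every marker is RR or RS
    with equal probability before selection.  Returns an
    (offspring x marker) uint8 matrix with values ``RR`` (2) and ``RS`` (1),
    markers in map order.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    chrom_names = [c.name for c in gmap.chromosomes]
    if design.locus_chrom not in chrom_names:
        raise ValueError(f"resistance locus chromosome {design.locus_chrom!r} off the map")
    locus_len = gmap.chrom(design.locus_chrom).genetic_length
    if not 0.0 <= design.locus_gpos <= locus_len:
        raise ValueError("resistance locus genetic position off the map")

    rng = np.random.default_rng(seed)
    frame = gmap.frame()
    by_chrom = [
        (gmap.chrom(c).genetic_length, frame.index[frame["chrom"] == c].to_numpy(),
         frame.loc[frame["chrom"] == c, "gpos"].to_numpy())
        for c in chrom_names
    ]
    geno = np.empty((n_offspring, len(gmap.markers)), dtype=np.uint8)
    for k in range(n_offspring):
        for glen, cols, gpos in by_chrom:
            r_allele = _gamete_alleles(gpos, glen, rng)
            geno[k, cols] = np.where(r_allele, RR, RS)
    return geno


def apply_selection(
    genotypes: np.ndarray,
    gmap: GenomeMap,
    design: CrossDesign,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Apply survival selection at the marker nearest the resistance locus.

    Each offspring survives with the penetrance of its genotype at that
    marker.  An empty survivor set is a legitimate outcome reported as an
    empty (0 x markers) matrix with a warning, not an exception.
    """
    rng = np.random.default_rng(seed)
    locus_col = gmap.nearest_marker(design.locus_chrom, design.locus_gpos)
    locus_geno = genotypes[:, locus_col]
    p = np.where(
        locus_geno == RR, design.penetrance.rr, design.penetrance.rs
    )  # SS cannot occur in a backcross to the resistant parent
    survives = rng.random(genotypes.shape[0]) < p
    survivors = genotypes[survives]
    if survivors.shape[0] == 0:
        warnings.warn("selection left no survivors", stacklevel=2)
    return survivors


# ---------------------------------------------------------------------------
# read counts


def _biased_freq(p: np.ndarray, bias: float) -> np.ndarray:
    """Allele-specific-expression distortion: p' = b*p / (b*p + (1-p))."""
    if bias < 0:
        raise ValueError("ase_bias must be >= 0")
    num = bias * p
    den = num + (1.0 - p)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def _draw_counts(
    freqs: np.ndarray,
    mean_coverage: float,
    overdispersion: float,
    ase_bias: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    n = freqs.shape[0]
    if overdispersion == 0:
        cov = rng.poisson(mean_coverage, size=n)
    else:
        # variance = m + d * m^2  =>  NB with shape 1/d
        shape = 1.0 / overdispersion
        cov = rng.negative_binomial(shape, shape / (shape + mean_coverage), size=n)
    res = rng.binomial(cov, _biased_freq(freqs, ase_bias))
    return res, cov - res


def simulate_bulk_counts(
    survivors: np.ndarray,
    gmap: GenomeMap,
    mean_coverage: float,
    overdispersion: float = 0.0,
    ase_bias: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    sample: str = "bulk",
) -> BulkCounts:
    """Pooled read counts for the selected bulk.

    The pool's resistant-allele frequency at each marker is the mean
    resistant-allele dosage of the survivors divided by two; coverage is
    negative-binomial (Poisson when overdispersion is 0) and resistant-read
    counts binomial at the ASE-distorted frequency.
    """
    if survivors.shape[0] == 0:
        raise ValueError("cannot pool an empty survivor set")
    rng = np.random.default_rng(seed)
    freqs = survivors.mean(axis=0) / 2.0
    res, sus = _draw_counts(freqs, mean_coverage, overdispersion, ase_bias, rng)
    frame = gmap.frame()[["marker", "unigene", "chrom", "upos"]].copy()
    frame["sample"] = sample
    frame["res_count"] = res
    frame["sus_count"] = sus
    return BulkCounts(frame=frame)


def simulate_parent_counts(
    gmap: GenomeMap,
    mean_coverage: float,
    overdispersion: float = 0.0,
    purity: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> BulkCounts:
    """Read counts for the two (inbred) parental samples.

    The resistant parent carries the resistant allele at frequency
    ``purity`` at every marker; the susceptible parent at ``1 - purity``.
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError("purity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(gmap.markers)
    base = gmap.frame()[["marker", "unigene", "chrom", "upos"]]
    frames = []
    for sample, p in (("res_parent", purity), ("sus_parent", 1.0 - purity)):
        res, sus = _draw_counts(
            np.full(n, p), mean_coverage, overdispersion, 1.0, rng
        )
        f = base.copy()
        f["sample"] = sample
        f["res_count"] = res
        f["sus_count"] = sus
        frames.append(f)
    return BulkCounts(frame=pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# coverage tracks and deletions


def simulate_coverage_tracks(
    unigene_lengths: dict[str, int],
    mean_coverage: float,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-base Poisson coverage tracks (resistant, susceptible) per unigene."""
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    rng = np.random.default_rng(seed)
    tracks = {}
    for unigene, length in unigene_lengths.items():
        if length < 1:
            raise ValueError(f"unigene {unigene} has non-positive length")
        tracks[unigene] = (
            rng.poisson(mean_coverage, size=length),
            rng.poisson(mean_coverage, size=length),
        )
    return tracks


def inject_deletion(
    tracks: dict[str, tuple[np.ndarray, np.ndarray]],
    unigene: str,
    interval: tuple[int, int],
    counts: BulkCounts | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Zero the resistant-bulk coverage inside an interval of one unigene.

    ``interval`` is 1-based inclusive in transcript coordinates; an empty
    interval (start > end) is the identity.  The susceptible track is left
    untouched.  When ``counts`` is given, bulk-sample reads at markers
    falling inside the interval are zeroed in place as well (no reads map
    into a deleted region).  Returns a new track dict; input arrays are not
    modified.
    """
    start, end = interval
    if unigene not in tracks:
        raise KeyError(f"unknown unigene {unigene!r}")
    res, sus = tracks[unigene]
    if start > end:  # empty interval: identity
        return tracks
    if start < 1 or end > res.shape[0]:
        raise ValueError(
            f"interval {interval} outside unigene {unigene} (length {res.shape[0]})"
        )
    new_res = res.copy()
    new_res[start - 1 : end] = 0
    out = dict(tracks)
    out[unigene] = (new_res, sus)
    if counts is not None:
        mask = (
            (counts.frame["unigene"] == unigene)
            & (counts.frame["sample"] == "bulk")
            & counts.frame["upos"].between(start, end)
        )
        counts.frame.loc[mask, ["res_count", "sus_count"]] = 0
    return out


# ---------------------------------------------------------------------------
# homology hit tables


def _gene_of(unigene: str) -> str:
    return "bmgene_" + unigene[2:].lower()


def reference_gene_table(gmap: GenomeMap) -> pd.DataFrame:
    """Positions of the true reference orthologs, one gene per unigene.

    The reference shares the map's coordinate system; each gene spans its
    unigene's markers padded by 100 bp.
    """
    frame = gmap.frame()
    rows = []
    for unigene, grp in frame.groupby("unigene", sort=False):
        rows.append(
            {
                "gene": _gene_of(unigene),
                "chrom": grp["chrom"].iloc[0],
                "start": max(1, int(grp["ppos"].min()) - 100),
                "end": int(grp["ppos"].max()) + 100,
                "strand": "+",
            }
        )
    return pd.DataFrame(rows)


def generate_hit_tables(
    gmap: GenomeMap,
    missing_fraction: float = 0.0,
    decoy_paralogs: int = 0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directional homology hit tables whose RBH is the true unigene-gene map.

    Each retained unigene gets a reciprocal best hit to its true reference
    gene plus ``decoy_paralogs`` hits to other genes at strictly lower
    bitscores; a seeded random ``missing_fraction`` of unigenes get no hits
    in either direction.
    """
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction must be in [0, 1)")
    if decoy_paralogs < 0:
        raise ValueError("decoy_paralogs must be >= 0")
    rng = np.random.default_rng(seed)
    unigenes = gmap.unigenes()
    keep = rng.random(len(unigenes)) >= missing_fraction
    kept = [u for u, k in zip(unigenes, keep) if k]
    genes = [_gene_of(u) for u in unigenes]
    best_score = {u: round(float(rng.uniform(400.0, 600.0)), 1) for u in kept}
    ident = {u: round(float(rng.uniform(90.0, 99.0)), 1) for u in kept}
    fwd_rows, rev_rows = [], []
    for u in kept:
        true_gene = _gene_of(u)
        fwd_rows.append((u, true_gene, ident[u], 500, 1e-150, best_score[u]))
        rev_rows.append((true_gene, u, ident[u], 500, 1e-150, best_score[u]))
    if decoy_paralogs:
        unigene_of_gene = {_gene_of(u): u for u in unigenes}
        for u in kept:
            true_gene = _gene_of(u)
            others = [g for g in genes if g != true_gene]
            picks = rng.choice(
                len(others), size=min(decoy_paralogs, len(others)), replace=False
            )
            for gi in picks:
                other = others[gi]
                # strictly below the true best in BOTH directions, so decoys
                # can never displace a reciprocal best hit
                cap = min(best_score[u], best_score.get(unigene_of_gene[other], np.inf))
                score = round(cap * float(rng.uniform(0.3, 0.8)), 1)
                fwd_rows.append((u, other, ident[u] - 10, 400, 1e-40, score))
                rev_rows.append((other, u, ident[u] - 10, 400, 1e-40, score))
    cols = ["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]
    return pd.DataFrame(fwd_rows, columns=cols), pd.DataFrame(rev_rows, columns=cols)


# ---------------------------------------------------------------------------
# whole-experiment convenience


@dataclass
class Experiment:
    """Everything one synthetic BSA experiment produces."""

    gmap: GenomeMap
    design: CrossDesign
    survivors: np.ndarray
    counts: BulkCounts          # three samples: res_parent, sus_parent, bulk
    hits_fwd: pd.DataFrame
    hits_rev: pd.DataFrame
    genes: pd.DataFrame
    locus_unigene: str
    n_offspring: int


def simulate_experiment(
    n_chrom: int = 5,
    unigenes_per_chrom: int = 40,
    snps_per_unigene: int = 3,
    genetic_len: float = 1.0,
    physical_len: int = 3_000_000,
    n_offspring: int = 2_000,
    penetrance: PenetranceModel | None = None,
    locus_chrom: str = "chr3",
    locus_gpos: float | None = None,
    mean_coverage: float = 200.0,
    overdispersion: float = 0.0,
    ase_bias: float = 1.0,
    missing_fraction: float = 0.0,
    decoy_paralogs: int = 2,
    seed: int = 0,
) -> Experiment:
    """Run the full synthetic pipeline up to the allele-count tables.

    Child seeds for each stochastic stage are spawned from one seed
    sequence, so a single integer reproduces the whole experiment.
    """
    ss = np.random.SeedSequence(seed)
    s_map, s_cross, s_sel, s_bulk, s_parent, s_hits = ss.spawn(6)
    penetrance = penetrance or PenetranceModel()
    if locus_gpos is None:
        locus_gpos = genetic_len / 2.0  # mid-chromosome
    gmap = build_genome_map(
        n_chrom, unigenes_per_chrom, snps_per_unigene,
        genetic_len, physical_len, seed=s_map,
    )
    design = CrossDesign(
        cross_type="BC1", locus_chrom=locus_chrom, locus_gpos=locus_gpos,
        penetrance=penetrance,
    )
    genotypes = simulate_backcross(gmap, design, n_offspring, seed=s_cross)
    survivors = apply_selection(genotypes, gmap, design, seed=s_sel)
    bulk = simulate_bulk_counts(
        survivors, gmap, mean_coverage, overdispersion, ase_bias, seed=s_bulk
    )
    parents = simulate_parent_counts(gmap, mean_coverage, overdispersion, seed=s_parent)
    counts = BulkCounts(frame=pd.concat([parents.frame, bulk.frame], ignore_index=True))
    hits_fwd, hits_rev = generate_hit_tables(
        gmap, missing_fraction, decoy_paralogs, seed=s_hits
    )
    genes = reference_gene_table(gmap)
    locus_unigene = gmap.markers[gmap.nearest_marker(locus_chrom, locus_gpos)].unigene
    return Experiment(
        gmap=gmap, design=design, survivors=survivors, counts=counts,
        hits_fwd=hits_fwd, hits_rev=hits_rev, genes=genes,
        locus_unigene=locus_unigene, n_offspring=n_offspring,
    )
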
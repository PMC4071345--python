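import numpy as np
import pandas as pd
import pytest

from bsamap import io, simdata, variants
from bsamap.genetics import PenetranceModel
from bsamap.simdata import Chromosome, CrossDesign, GenomeMap, Marker


def two_marker_map(distance: float, chrom_len: float = 1.0) -> GenomeMap:
    """A single chromosome with two unigenes ``distance`` Morgans apart."""
    return GenomeMap(
        chromosomes=(Chromosome("chr1", chrom_len, 1_000_000),),
        markers=(
            Marker("uA:snp1", "uA", "chr1", 0.2, 100_000, 101),
            Marker("uB:snp1", "uB", "chr1", 0.2 + distance, 500_000, 101),
        ),
    )


def informative_snps_for(exp: simdata.Experiment, **kwargs) -> list:
    """Call informative SNPs straight from a simulated experiment."""
    records = variants.records_from_frame(io.counts_table(exp.counts))
    return [
        s
        for r in records
        if (s := variants.call_informative(r, **kwargs)) is not None
    ]


@pytest.fixture(scope="session")
def default_experiment() -> simdata.Experiment:
    """A mid-sized selected experiment reused by read-only tests."""
    return simdata.simulate_experiment(
        n_chrom=5,
        unigenes_per_chrom=10,
        snps_per_unigene=3,
        genetic_len=0.25,  # anchor spacing 0.025 M, as in the full-size default
        n_offspring=1_000,
        penetrance=PenetranceModel(rr=0.35, rs=0.0, ss=0.0),
        mean_coverage=200.0,
        seed=11,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_snp(
    unigene: str = "u1",
    pos: int = 1,
    bulk_freq: float = 1.0,
    fixed: bool | None = None,
    threshold: float = 0.95,
) -> variants.InformativeSNP:
    """Hand-build an InformativeSNP without going through count tables."""
    rec = variants.VariantRecord(
        unigene=unigene,
        pos=pos,
        ref="A",
        alt="G",
        counts={"res_parent": (0, 20), "sus_parent": (20, 0), "bulk": (0, 20)},
    )
    if fixed is None and not np.isnan(bulk_freq):
        fixed = bulk_freq > threshold
    return variants.InformativeSNP(
        record=rec, res_allele="alt", bulk_freq=bulk_freq, fixed=fixed
    )
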
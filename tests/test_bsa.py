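import math

import numpy as np
import pandas as pd
import pytest

from conftest import informative_snps_for, make_snp
from bsamap import simdata
from bsamap.bsa import (
    Window,
    anchor_unigenes,
    bsa_index,
    call_regions,
    reciprocal_best_hits,
    rolling_windows,
    scan,
)
from bsamap.genetics import PenetranceModel


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_best_hit(hits: pd.DataFrame, query: str):
    """Best hit of one query by explicit comparison of every row."""
    best = None
    for row in hits.itertuples():
        if row.qseqid != query:
            continue
        key = (-row.bitscore, row.evalue, row.sseqid)
        if best is None or key < best[0]:
            best = (key, row.sseqid)
    return None if best is None else best[1]


def brute_force_rbh(hits_ab, hits_ba):
    pairs = []
    for q in sorted(set(hits_ab["qseqid"])):
        g = brute_force_best_hit(hits_ab, q)
        if g is not None and brute_force_best_hit(hits_ba, g) == q:
            pairs.append((q, g))
    return pairs


def brute_force_regions(means: list[float], threshold: float):
    """Run-length oracle over a window-mean sequence: (start_idx, end_idx) runs."""
    runs, start = [], None
    for i, m in enumerate(means):
        if m > threshold:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start, i - 1))
                start = None
    if start is not None:
        runs.append((start, len(means) - 1))
    return runs


def windows_from_indexes(indexes, k=3, chrom="chr1"):
    """Hand-build Window objects over anchors at 1000*i..1000*i+100."""
    out = []
    for i in range(len(indexes) - k + 1):
        out.append(
            Window(
                chrom=chrom,
                start_rank=i + 1,
                unigenes=tuple(f"u{j}" for j in range(i, i + k)),
                span=(1000 * i, 1000 * (i + k - 1) + 100),
                mean_index=float(np.mean(indexes[i : i + k])),
            )
        )
    return out


# ---------------------------------------------------------------------------


class TestBsaIndex:
    def test_all_fixed(self):
        snps = [make_snp(bulk_freq=1.0, pos=i) for i in range(1, 5)]
        assert bsa_index(snps).index == 1.0

    def test_none_fixed(self):
        snps = [make_snp(bulk_freq=0.5, pos=i) for i in range(1, 6)]
        assert bsa_index(snps).index == 0.0

    def test_three_quarters(self):
        snps = [make_snp(bulk_freq=f, pos=i) for i, f in enumerate([1.0, 0.99, 0.97, 0.5], 1)]
        u = bsa_index(snps)
        assert (u.n_snps, u.n_fixed) == (4, 3)
        assert u.index == 0.75

    def test_mixed_unigenes_rejected(self):
        with pytest.raises(ValueError, match="multiple unigenes"):
            bsa_index([make_snp(unigene="a"), make_snp(unigene="b", pos=2)])

    def test_min_snps_undefined(self):
        u = bsa_index([make_snp(bulk_freq=1.0)], min_snps=2)
        assert math.isnan(u.index)
        assert not u.defined

    def test_undefined_frequency_snps_excluded(self):
        snps = [make_snp(bulk_freq=1.0, pos=1), make_snp(bulk_freq=float("nan"), pos=2)]
        u = bsa_index(snps)
        assert u.n_snps == 1 and u.index == 1.0

    def test_bounds_and_monotonicity(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 12))
            freqs = rng.random(n)
            snps = [make_snp(bulk_freq=f, pos=i + 1) for i, f in enumerate(freqs)]
            u = bsa_index(snps)
            assert 0.0 <= u.index <= 1.0
            assert u.index == pytest.approx(sum(f > 0.95 for f in freqs) / n)


class TestReciprocalBestHits:
    def hits(self, rows):
        return pd.DataFrame(
            rows, columns=["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]
        )

    def test_mutual_best(self):
        ab = self.hits([("u1", "g5", 99, 500, 1e-100, 900), ("u1", "g2", 90, 400, 1e-20, 300)])
        ba = self.hits([("g5", "u1", 99, 500, 1e-100, 900), ("g2", "u9", 90, 400, 1e-20, 300)])
        pairs = reciprocal_best_hits(ab, ba)
        assert list(map(tuple, pairs.to_numpy())) == [("u1", "g5")]

    def test_asymmetry_excluded(self):
        ab = self.hits([("u1", "g5", 99, 500, 1e-100, 900)])
        ba = self.hits([("g5", "u9", 99, 500, 1e-100, 950), ("g5", "u1", 99, 500, 1e-100, 900)])
        assert reciprocal_best_hits(ab, ba).empty

    def test_tie_broken_by_evalue_then_id(self):
        ab = self.hits(
            [("u1", "gB", 99, 500, 1e-100, 900), ("u1", "gA", 99, 500, 1e-100, 900)]
        )
        ba = self.hits([("gA", "u1", 99, 500, 1e-100, 900), ("gB", "u1", 99, 500, 1e-100, 900)])
        pairs = reciprocal_best_hits(ab, ba)
        assert list(pairs["gene"]) == ["gA"]

    def test_bruteforce_oracle_random_tables(self, rng):
        for _ in range(100):
            n_u, n_g = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            rows_ab, rows_ba = [], []
            for _ in range(int(rng.integers(3, 25))):
                q = f"u{rng.integers(n_u)}"
                s = f"g{rng.integers(n_g)}"
                rows_ab.append((q, s, 95.0, 400, 10.0 ** -int(rng.integers(5, 100)),
                                float(rng.integers(100, 999))))
            for _ in range(int(rng.integers(3, 25))):
                q = f"g{rng.integers(n_g)}"
                s = f"u{rng.integers(n_u)}"
                rows_ba.append((q, s, 95.0, 400, 10.0 ** -int(rng.integers(5, 100)),
                                float(rng.integers(100, 999))))
            ab, ba = self.hits(rows_ab), self.hits(rows_ba)
            got = list(map(tuple, reciprocal_best_hits(ab, ba).to_numpy()))
            assert sorted(got) == brute_force_rbh(ab, ba)

    def test_empty_tables(self):
        empty = self.hits([])
        assert reciprocal_best_hits(empty, empty).empty


class TestAnchorUnigenes:
    GENES = pd.DataFrame(
        {
            "gene": ["g1", "g2", "g3", "g4"],
            "chrom": ["chrA", "chrA", "chrA", "chrB"],
            "start": [500, 100, 900, 50],
            "end": [600, 200, 1000, 80],
            "strand": ["+", "+", "-", "+"],
        }
    )

    def pairs(self, items):
        return pd.DataFrame(items, columns=["unigene", "gene"])

    def test_rank_by_start(self):
        anchors = anchor_unigenes(self.pairs([("u1", "g1"), ("u2", "g2"), ("u3", "g3")]), self.GENES)
        assert list(anchors["unigene"]) == ["u2", "u1", "u3"]
        assert list(anchors["rank"]) == [1, 2, 3]

    def test_independent_ranks_per_chromosome(self):
        anchors = anchor_unigenes(
            self.pairs([("u1", "g1"), ("u2", "g4")]), self.GENES
        )
        assert list(anchors["rank"]) == [1, 1]

    def test_shuffle_invariance(self):
        fwd = anchor_unigenes(self.pairs([("u1", "g1"), ("u2", "g2")]), self.GENES)
        rev = anchor_unigenes(self.pairs([("u2", "g2"), ("u1", "g1")]), self.GENES)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_missing_gene_warns_and_excluded(self):
        with pytest.warns(UserWarning, match="excluded"):
            anchors = anchor_unigenes(
                self.pairs([("u1", "g1"), ("ux", "missing")]), self.GENES
            )
        assert list(anchors["unigene"]) == ["u1"]


class TestRollingWindows:
    def anchored(self, indexes, chrom="chr1"):
        n = len(indexes)
        return pd.DataFrame(
            {
                "unigene": [f"u{i}" for i in range(n)],
                "gene": [f"g{i}" for i in range(n)],
                "chrom": chrom,
                "start": [1000 * i for i in range(n)],
                "end": [1000 * i + 100 for i in range(n)],
                "rank": range(1, n + 1),
                "index": indexes,
            }
        )

    def test_single_window_mean(self):
        (w,) = rolling_windows(self.anchored([1.0, 0.8, 0.6]), 3)
        assert w.mean_index == pytest.approx(0.8)

    def test_constant_smoothing_identity(self):
        ws = rolling_windows(self.anchored([0.4] * 7), 3)
        assert all(w.mean_index == pytest.approx(0.4) for w in ws)

    def test_window_count(self):
        assert len(rolling_windows(self.anchored([0.1] * 10), 3)) == 8

    def test_short_chromosome_yields_none(self):
        assert rolling_windows(self.anchored([0.5, 0.5]), 3) == []

    def test_nan_indexes_excluded(self):
        ws = rolling_windows(self.anchored([1.0, float("nan"), 1.0, 1.0]), 3)
        assert len(ws) == 1
        assert ws[0].mean_index == 1.0

    def test_means_bounded_by_members(self, rng):
        for _ in range(100):
            idx = rng.random(int(rng.integers(3, 15)))
            for w in rolling_windows(self.anchored(list(idx)), 3):
                members = [idx[int(u[1:])] for u in w.unigenes]
                assert min(members) - 1e-12 <= w.mean_index <= max(members) + 1e-12

    def test_bad_window_size(self):
        with pytest.raises(ValueError):
            rolling_windows(self.anchored([0.5] * 4), 0)


class TestCallRegions:
    def test_hand_enumeration_example(self):
        idx = [0.1, 0.2, 1.0, 1.0, 0.9, 0.2, 0.1, 0.0]
        ws = windows_from_indexes(idx, 3)
        means = [w.mean_index for w in ws]
        np.testing.assert_allclose(
            means, [0.4333333, 0.7333333, 0.9666667, 0.7, 0.4, 0.1], atol=1e-6
        )
        regions = call_regions(ws, 0.60)
        assert len(regions) == 1
        (r,) = regions
        assert r.unigenes == ("u1", "u2", "u3", "u4", "u5")  # anchors 2..6
        assert r.n_unigenes == 5
        assert r.peak_mean == pytest.approx(0.9666667)

    def test_all_zero_no_regions(self):
        assert call_regions(windows_from_indexes([0.0] * 8, 3), 0.6) == []

    def test_all_one_single_region_spans_everything(self):
        ws = windows_from_indexes([1.0] * 8, 3)
        (r,) = call_regions(ws, 0.6)
        assert r.n_unigenes == 8
        assert (r.start, r.end) == (0, 7100)

    def test_threshold_is_strict(self):
        ws = windows_from_indexes([0.6, 0.6, 0.6], 3)
        assert call_regions(ws, 0.6) == []

    def test_bruteforce_run_length_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 50))
            idx = np.round(rng.random(n), 3)
            thr = float(rng.uniform(0.2, 0.8))
            ws = windows_from_indexes(list(idx), 3)
            regions = call_regions(ws, thr)
            runs = brute_force_regions([w.mean_index for w in ws], thr)
            assert len(regions) == len(runs)
            for region, (a, b) in zip(regions, runs):
                members = set()
                for w in ws[a : b + 1]:
                    members.update(w.unigenes)
                assert set(region.unigenes) == members
                assert region.peak_mean == pytest.approx(
                    max(w.mean_index for w in ws[a : b + 1])
                )


class TestScan:
    def test_parameter_recovery_default_scenario(self, default_experiment):
        exp = default_experiment
        snps = informative_snps_for(exp)
        result = scan(snps, exp.hits_fwd, exp.hits_rev, exp.genes)
        top = result.top_region()
        assert top is not None
        assert exp.locus_unigene in top.unigenes
        assert top.chrom == "chr3"

    def test_neutral_scenario_no_regions(self):
        exp = simdata.simulate_experiment(
            n_chrom=3, unigenes_per_chrom=15, n_offspring=400,
            penetrance=PenetranceModel.neutral(), locus_chrom="chr2",
            mean_coverage=200, seed=5,
        )
        snps = informative_snps_for(exp)
        result = scan(snps, exp.hits_fwd, exp.hits_rev, exp.genes)
        assert result.regions.empty

    def test_determinism(self, default_experiment):
        exp = default_experiment
        snps = informative_snps_for(exp)
        a = scan(snps, exp.hits_fwd, exp.hits_rev, exp.genes)
        b = scan(snps, exp.hits_fwd, exp.hits_rev, exp.genes)
        pd.testing.assert_frame_equal(a.indexes, b.indexes)
        pd.testing.assert_frame_equal(a.windows, b.windows)
        pd.testing.assert_frame_equal(a.regions, b.regions)

    def test_stage_errors_are_labelled(self, default_experiment):
        exp = default_experiment
        snps = informative_snps_for(exp)
        bad_genes = exp.genes.drop(columns=["start"])
        with pytest.raises(RuntimeError, match="stage 'anchor'"):
            scan(snps, exp.hits_fwd, exp.hits_rev, bad_genes)

    def test_index_table_bounded(self, default_experiment):
        exp = default_experiment
        snps = informative_snps_for(exp)
        result = scan(snps, exp.hits_fwd, exp.hits_rev, exp.genes)
        defined = result.indexes["index"].dropna()
        assert ((defined >= 0) & (defined <= 1)).all()
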
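"""Positional, CGI, clustering, shift and enrichment characterization."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from tdmrscan.profiles import (
    build_profile_matrix,
    cgi_gene_bias,
    cgi_genes,
    cluster_profiles,
    detect_cgi,
    detect_position_shift,
    enrichment,
    tss_distance_histogram,
)
from tdmrscan.types import DeltaTrack, GeneModel, Interval, TDMR


def tdmr(distance, direction="hypo_in_test", gene="g", start=0, end=100):
    sign = 1.0 if direction == "hypo_in_test" else -1.0
    t = TDMR("chr1", start, end, direction, sign * 3.0, 5)
    t.gene_id = gene
    t.tss_distance = distance
    return t


class TestHistogram:
    def test_example_binning(self):
        h = tss_distance_histogram([tdmr(d) for d in (-5900, -5800, 100, 200)])
        bins = dict(zip(h.edges[:-1].astype(int), h.proportions))
        assert bins[-6000] == pytest.approx(0.5)
        assert bins[0] == pytest.approx(0.5)

    def test_single_bin(self):
        h = tss_distance_histogram([tdmr(-100)] * 5)
        assert h.proportions.max() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tss_distance_histogram([])

    def test_unassigned_input_rejected(self):
        t = tdmr(0)
        t.tss_distance = None
        with pytest.raises(ValueError, match="gene-assigned"):
            tss_distance_histogram([t])

    def test_matches_naive_counting(self, rng):
        dists = rng.integers(-6000, 2500, size=1000)
        h = tss_distance_histogram([tdmr(int(d)) for d in dists])
        for i, (lo, hi) in enumerate(zip(h.edges[:-1], h.edges[1:])):
            naive = np.sum((dists >= lo) & (dists < hi)) / 1000
            assert h.proportions[i] == pytest.approx(naive)
        assert abs(h.proportions.sum() - 1) < 1e-9

    def test_order_invariance(self, rng):
        dists = rng.integers(-6000, 2500, size=100)
        a = tss_distance_histogram([tdmr(int(d)) for d in dists])
        b = tss_distance_histogram([tdmr(int(d)) for d in dists[::-1]])
        assert np.allclose(a.proportions, b.proportions)


def oracle_cgi(seq, min_len=200, min_gc=0.5, min_oe=0.6):
    """Naive full-scan oracle: union of all passing windows."""
    passing = []
    for s in range(len(seq) - min_len + 1):
        w = seq[s : s + min_len]
        nc, ng = w.count("C"), w.count("G")
        ncg = sum(1 for i in range(min_len - 1) if w[i : i + 2] == "CG")
        if (nc + ng) / min_len < min_gc or nc * ng == 0:
            continue
        if ncg * min_len / (nc * ng) >= min_oe:
            passing.append((s, s + min_len))
    merged = []
    for s, e in passing:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


class TestDetectCgi:
    def test_cg_repeat_is_one_island(self):
        seq = "CG" * 250
        assert detect_cgi(seq) == [(0, 500)]

    def test_poly_a_has_none(self):
        assert detect_cgi("A" * 500) == []

    def test_short_sequence_returns_empty(self):
        assert detect_cgi("CG" * 50) == []

    def test_mosaic_matches_naive_oracle(self, rng):
        parts = []
        for _ in range(6):
            if rng.random() < 0.5:
                parts.append("".join(rng.choice(list("CG"), size=rng.integers(80, 300))))
            else:
                parts.append("".join(rng.choice(list("AT"), size=rng.integers(80, 300))))
        seq = "".join(parts)
        assert detect_cgi(seq) == oracle_cgi(seq)

    def test_flank_invariance(self):
        island = "CG" * 150
        base = detect_cgi("A" * 300 + island + "A" * 300)
        longer = detect_cgi("A" * 300 + island + "A" * 900)
        assert base == longer


class TestCgiBias:
    def genes(self):
        return [GeneModel(f"g{i}", "chr1", 10_000 + 9000 * i, "+") for i in range(4)]

    def test_all_genes_cgi(self):
        genes = self.genes()
        cgis = [Interval("chr1", g.tss - 50, g.tss + 50) for g in genes]
        calls = [tdmr(0, "hypo_in_test", g.gene_id) for g in genes[:2]] + [
            tdmr(0, "hypo_in_control", g.gene_id) for g in genes[2:]
        ]
        props, _ = cgi_gene_bias(calls, genes, cgis)
        assert props == {"hypo_in_test": 1.0, "hypo_in_control": 1.0}

    def test_fisher_matches_hypergeometric(self):
        genes = self.genes()
        cgis = [Interval("chr1", genes[0].tss - 50, genes[0].tss + 50),
                Interval("chr1", genes[1].tss - 50, genes[1].tss + 50)]
        calls = [tdmr(0, "hypo_in_test", "g0"), tdmr(0, "hypo_in_test", "g1"),
                 tdmr(0, "hypo_in_control", "g2"), tdmr(0, "hypo_in_control", "g3")]
        props, p = cgi_gene_bias(calls, genes, cgis)
        assert props == {"hypo_in_test": 1.0, "hypo_in_control": 0.0}
        expected = stats.fisher_exact([[2, 0], [0, 2]], "two-sided")[1]
        assert p == pytest.approx(expected, abs=1e-12)

    def test_zero_flank_requires_tss_base(self):
        genes = self.genes()
        covers = Interval("chr1", genes[0].tss, genes[0].tss + 1)
        adjacent = Interval("chr1", genes[1].tss + 1, genes[1].tss + 10)
        assert cgi_genes(genes, [covers, adjacent], tss_flank=0) == {"g0"}


class TestClustering:
    def test_k1_single_cluster(self, rng):
        labels, _ = cluster_profiles(rng.normal(size=(10, 4)), k=1, seed=0)
        assert set(labels) == {0}

    def test_k_exceeding_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_profiles(rng.normal(size=(2, 4)), k=3, seed=0)

    def test_missing_values_rejected(self):
        m = np.ones((4, 4))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            cluster_profiles(m, k=2, seed=0)

    def test_noiseless_archetypes_perfectly_partitioned(self):
        protos = np.array([[4, 4, 4, 4], [4, 4, 0, 0], [-4, -4, 0, 0]], dtype=float)
        truth = np.repeat(np.arange(3), 20)
        matrix = protos[truth]
        labels, means = cluster_profiles(matrix, k=3, seed=1)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert means.shape == (3, 4)

    def test_partition_stable_across_seeds_on_separable_data(self):
        protos = np.array([[4, 4, 0, 0], [-4, -4, 0, 0], [4, 0, 4, 0]], dtype=float)
        truth = np.repeat(np.arange(3), 15)
        matrix = protos[truth]
        a, _ = cluster_profiles(matrix, k=3, seed=0)
        b, _ = cluster_profiles(matrix, k=3, seed=99)
        assert adjusted_rand_score(a, b) == 1.0


class TestProfileMatrix:
    def test_mean_delta_per_interval(self):
        track = DeltaTrack(
            "t", "c",
            pd.DataFrame({"contig": "chr1", "position": [0, 35, 70, 105], "delta": [1.0, 2.0, 3.0, 4.0]}),
        )
        calls = [tdmr(0, start=0, end=70), tdmr(0, start=70, end=140)]
        m = build_profile_matrix(calls, {"x": track})
        assert m["x"].tolist() == [pytest.approx(1.5), pytest.approx(3.5)]

    def test_interval_without_probes_rejected(self):
        track = DeltaTrack("t", "c", pd.DataFrame({"contig": ["chr1"], "position": [0], "delta": [1.0]}))
        with pytest.raises(ValueError, match="no probes"):
            build_profile_matrix([tdmr(0, start=500, end=600)], {"x": track})


def adult_track(positions, deltas):
    return DeltaTrack("AD", "A", pd.DataFrame({"contig": "chr1", "position": positions, "delta": deltas}))


class TestPositionShift:
    def sets(self, nsph, adult):
        return {"nsph": nsph, "adult": adult}

    def test_shift_pattern_flagged(self):
        nsph = [tdmr(-3000, "hypo_in_test", "g", 1000, 1500)]
        adult = [tdmr(800, "hypo_in_test", "g", 9000, 9500)]
        tracks = {"adult": adult_track([1100, 1200], [0.2, 0.1])}
        flag, ev = detect_position_shift("g", self.sets(nsph, adult), tracks)
        assert flag
        assert ev["lost_upstream"] and ev["gained_downstream"]

    def test_persistent_upstream_not_flagged(self):
        nsph = [tdmr(-3000, "hypo_in_test", "g", 1000, 1500)]
        adult = [tdmr(800, "hypo_in_test", "g", 9000, 9500)]
        tracks = {"adult": adult_track([1100, 1200], [5.0, 6.0])}  # still hypomethylated
        flag, _ = detect_position_shift("g", self.sets(nsph, adult), tracks)
        assert not flag

    def test_no_downstream_gain_not_flagged(self):
        nsph = [tdmr(-3000, "hypo_in_test", "g", 1000, 1500)]
        tracks = {"adult": adult_track([1100, 1200], [0.0, 0.0])}
        flag, _ = detect_position_shift("g", self.sets(nsph, []), tracks)
        assert not flag

    def test_unknown_gene_rejected(self):
        tracks = {"adult": adult_track([0], [0.0])}
        with pytest.raises(KeyError):
            detect_position_shift("absent", self.sets([], []), tracks)


def exact_upper_tail(N, K, n, k):
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return float(acc)


class TestEnrichment:
    def build(self, N, n, K, k):
        universe = {f"u{i}" for i in range(N)}
        ordered = sorted(universe)
        query = set(ordered[:n])
        term = set(ordered[:k]) | set(ordered[n : n + (K - k)])
        return query, {"t": term}, universe

    def test_zero_overlap_p_one(self):
        query, ann, uni = self.build(20, 5, 5, 0)
        (r,) = enrichment(query, ann, uni)
        assert r.p == pytest.approx(1.0)

    def test_exact_summation_example(self):
        query, ann, uni = self.build(100, 10, 10, 5)
        (r,) = enrichment(query, ann, uni)
        assert r.p == pytest.approx(exact_upper_tail(100, 10, 10, 5), abs=1e-12)

    def test_bh_all_ones(self):
        uni = {f"u{i}" for i in range(10)}
        ann = {f"t{i}": set() for i in range(5)}
        results = enrichment(set(list(uni)[:3]), ann, uni)
        assert all(r.p == 1.0 and r.q == 1.0 for r in results)

    def test_ease_reduces_overlap(self):
        query, ann, uni = self.build(50, 10, 10, 4)
        (fisher,) = enrichment(query, ann, uni, method="fisher")
        (ease,) = enrichment(query, ann, uni, method="ease")
        assert ease.p == pytest.approx(exact_upper_tail(50, 10, 10, 3), abs=1e-12)
        assert ease.p > fisher.p

    def test_ease_single_overlap_is_one(self):
        query, ann, uni = self.build(50, 10, 10, 1)
        (ease,) = enrichment(query, ann, uni, method="ease")
        assert ease.p == 1.0

    def test_stray_query_genes_rejected(self):
        with pytest.raises(ValueError, match="stray"):
            enrichment({"stray"}, {"t": set()}, {"u0"})

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        uni = {f"u{i}" for i in range(40)}
        ordered = sorted(uni)
        ann = {
            f"t{i}": set(rng.choice(ordered, size=8, replace=False)) for i in range(6)
        }
        results = enrichment(set(ordered[:10]), ann, uni)
        assert all(r.q >= r.p for r in results)
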
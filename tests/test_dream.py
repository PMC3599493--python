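"""Restriction-assay simulator: site finding, digestion, selection, readout."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdmrscan import GenomeAssembly, MethylomeProfile
from tdmrscan.dream import (
    build_probes,
    digest,
    digest_and_select,
    find_recognition_sites,
    select_amplifiable,
    simulate_intensities,
)
from tdmrscan.types import (
    CONTIG_END,
    HPY_END,
    TAQ_END,
    ProbeSet,
    RestrictionFragment,
)


class TestFindSites:
    @pytest.mark.parametrize(
        "seq, motif, expected",
        [
            ("ACGTTACGT", "ACGT", [0, 5]),
            ("TTTT", "ACGT", []),
            ("AAAA", "AA", [0, 1, 2]),  # overlapping occurrences all reported
            ("", "ACGT", []),
        ],
    )
    def test_examples(self, seq, motif, expected):
        assert find_recognition_sites(seq, motif) == expected

    def test_invalid_motif_rejected(self):
        with pytest.raises(ValueError):
            find_recognition_sites("ACGT", "")
        with pytest.raises(ValueError):
            find_recognition_sites("ACGT", "ACNT")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        naive = [i for i in range(len(seq) - 3) if seq[i : i + 4] == "ACGT"]
        assert find_recognition_sites(seq, "ACGT") == naive


class TestDigest:
    def test_unmethylated_site_cuts(self, single_site_contig):
        genome, methylome = single_site_contig
        for mode in ("deterministic_expected", "sampled"):
            frags, w = digest("chr1", genome["chr1"], methylome(0.0), mode=mode, seed=0)
            spans = sorted((f.start, f.end) for f in frags)
            assert spans == [(0, 41), (41, 100)]
            assert np.allclose(w, 1.0)

    def test_fully_methylated_site_uncut(self, single_site_contig):
        genome, methylome = single_site_contig
        for mode in ("deterministic_expected", "sampled"):
            frags, w = digest("chr1", genome["chr1"], methylome(1.0), mode=mode, seed=0)
            assert [(f.start, f.end) for f in frags] == [(0, 100)]
            assert frags[0].left_end == CONTIG_END and frags[0].right_end == CONTIG_END

    def test_expected_weights_are_cut_probabilities(self, single_site_contig):
        genome, methylome = single_site_contig
        frags, w = digest("chr1", genome["chr1"], methylome(0.3), mode="deterministic_expected")
        by_span = dict(zip([(f.start, f.end) for f in frags], w))
        assert by_span[(0, 41)] == pytest.approx(0.7)
        assert by_span[(41, 100)] == pytest.approx(0.7)
        assert by_span[(0, 100)] == pytest.approx(0.3)

    def test_missing_cpg_entry_names_position(self, single_site_contig):
        genome, _ = single_site_contig
        empty = MethylomeProfile("s", {"chr1": {}})
        with pytest.raises(KeyError, match="41"):
            digest("chr1", genome["chr1"], empty)

    def test_sampled_cut_rates_match_binomial(self, rng):
        # several sites with distinct methylation; cut rate ~ Bin(n, 1-m)
        seq = "".join("A" * 46 + "ACGT" for _ in range(4)) + "A" * 50
        sites = find_recognition_sites(seq, "ACGT")
        ms = [0.0, 0.25, 0.6, 0.9]
        meth = MethylomeProfile("s", {"c": {s + 1: m for s, m in zip(sites, ms)}})
        n = 10_000
        counts = np.zeros(len(sites))
        for i in range(n):
            frags, _ = digest("c", seq, meth, mode="sampled", seed=i)
            cutpos = {f.start for f in frags} | {f.end for f in frags}
            counts += [s + 1 in cutpos for s in sites]
        for cnt, m in zip(counts, ms):
            p = 1 - m
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(cnt - n * p) <= 3 * sigma + 1e-9

    def test_sampled_fragments_partition_contig(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        cpgs = {i + 1: rng.random() for i in find_recognition_sites(seq, "ACGT")}
        meth = MethylomeProfile("s", {"c": cpgs})
        frags, _ = digest("c", seq, meth, mode="sampled", seed=7)
        spans = sorted((f.start, f.end) for f in frags)
        assert spans[0][0] == 0 and spans[-1][1] == len(seq)
        for (s0, e0), (s1, e1) in zip(spans[:-1], spans[1:]):
            assert e0 == s1

    def test_lower_methylation_never_lowers_terminal_weight(self, single_site_contig):
        genome, methylome = single_site_contig
        weights = []
        for m in (0.9, 0.5, 0.1):
            frags, w = digest("chr1", genome["chr1"], methylome(m))
            by_span = dict(zip([(f.start, f.end) for f in frags], w))
            weights.append(by_span[(0, 41)])
        assert weights == sorted(weights)


class TestSelect:
    def frag(self, start, end, left, right):
        return RestrictionFragment("c", start, end, left, right)

    def test_selection_rules(self):
        frags = [
            self.frag(0, 200, HPY_END, TAQ_END),    # kept
            self.frag(0, 200, TAQ_END, TAQ_END),    # same-adaptor: dropped
            self.frag(0, 200, HPY_END, HPY_END),    # same-adaptor: dropped
            self.frag(0, 200, CONTIG_END, TAQ_END), # contig end: dropped
            self.frag(0, 30, TAQ_END, HPY_END),     # too short
            self.frag(0, 2000, TAQ_END, HPY_END),   # too long
        ]
        lib = select_amplifiable(frags, np.ones(len(frags)))
        assert [(f.start, f.end) for f in lib.fragments] == [(0, 200)]

    def test_bad_size_range_rejected(self):
        with pytest.raises(ValueError):
            select_amplifiable([], np.array([]), size_range=(1000, 40))

    def test_exhaustive_small_contig_matches_enumeration(self):
        # 3 HpyCH4IV and 2 TaqI sites at fixed positions, partial methylation
        parts = {100: "ACGT", 220: "TCGA", 400: "ACGT", 650: "ACGT", 900: "TCGA"}
        seq = list("A" * 1100)
        for p, motif in parts.items():
            seq[p : p + 4] = motif
        seq = "".join(seq)
        hpy = find_recognition_sites(seq, "ACGT")
        taq = find_recognition_sites(seq, "TCGA")
        assert (len(hpy), len(taq)) == (3, 2)
        meth = MethylomeProfile("s", {"c": {s + 1: 0.5 for s in hpy} | {s + 1: 0.5 for s in taq}})
        frags, w = digest("c", seq, meth)
        lib = select_amplifiable(frags, w, size_range=(40, 1000))
        got = sorted((f.start, f.end) for f in lib.fragments)

        # oracle: every (HpyCH4IV cut, TaqI cut) pair with no TaqI cut strictly
        # between (TaqI always cuts, so no fragment spans one), in size range
        hcuts = [s + 1 for s in hpy]
        tcuts = [t + 1 for t in taq]
        expected = set()
        for h in hcuts:
            for t in tcuts:
                a, b = min(h, t), max(h, t)
                if any(a < x < b for x in tcuts):
                    continue
                if 40 <= b - a <= 1000:
                    expected.add((a, b))
        assert got == sorted(expected)


class TestIntensities:
    def make_lib(self, spans, weights):
        frags = [RestrictionFragment("c", s, e, HPY_END, TAQ_END) for s, e in spans]
        from tdmrscan.types import FragmentLibrary

        return FragmentLibrary("s", frags, np.asarray(weights, dtype=float))

    def test_background_and_gain(self):
        probes = ProbeSet(np.array(["c", "c"], dtype=object), np.array([0, 500]))
        lib = self.make_lib([(480, 700)], [1.0])
        im = simulate_intensities(lib, probes, noise=(2.0, 7.0, 0.0), n_replicates=2)
        # probe at 0 overlaps nothing -> exactly b; probe at 500 inside the fragment -> b + g
        assert np.allclose(im.values[0], 2.0)
        assert np.allclose(im.values[1], 9.0)

    def test_zero_sigma_is_deterministic(self):
        probes = ProbeSet(np.array(["c"], dtype=object), np.array([10]))
        lib = self.make_lib([(0, 100)], [0.5])
        a = simulate_intensities(lib, probes, noise=(1, 10, 0.0), seed=1)
        b = simulate_intensities(lib, probes, noise=(1, 10, 0.0), seed=2)
        assert np.array_equal(a.values, b.values)

    def test_lognormal_moments(self):
        probes = ProbeSet(np.array(["c"], dtype=object), np.array([50]))
        lib = self.make_lib([(0, 200)], [0.8])
        sigma, n = 0.3, 10_000
        im = simulate_intensities(lib, probes, noise=(2.0, 10.0, sigma), n_replicates=n, seed=3)
        logs = np.log(im.values[0])
        mu = np.log(2.0 + 10.0 * 0.8)
        assert abs(logs.mean() - mu) <= 3 * sigma / np.sqrt(n)

    def test_empty_probeset_rejected(self):
        lib = self.make_lib([(0, 100)], [1.0])
        empty = ProbeSet(np.array([], dtype=object), np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty probe set"):
            simulate_intensities(lib, empty, seed=0)


def test_probes_tile_promoter_windows(small_genome):
    _, genes, _ = small_genome
    probes = build_probes(genes, step=35, length=25)
    starts = probes.start
    assert np.all(np.diff(starts) > 0)
    windows = [g.promoter_window for g in genes]
    for p in starts[:: len(starts) // 50 + 1]:
        assert any(s <= p and p + 25 <= e for s, e in windows)


def test_unmethylated_promoter_reads_brighter(small_genome):
    """End to end at sigma=0: fully unmethylated promoter gives more signal."""
    genome, genes, _ = small_genome
    g = genes[0]
    s, e = g.promoter_window
    base = {"chr1": {}}
    seq = genome["chr1"]
    i = seq.find("CG")
    while i >= 0:
        base["chr1"][i] = 1.0
        i = seq.find("CG", i + 1)
    lo = {c: dict(d) for c, d in base.items()}
    for p in list(lo["chr1"]):
        if s <= p < e:
            lo["chr1"][p] = 0.0
    m_hi = MethylomeProfile("hi", base)
    m_lo = MethylomeProfile("lo", lo)
    probes = build_probes([g])
    out = {}
    for m in (m_hi, m_lo):
        lib = digest_and_select(genome, m)
        out[m.sample_id] = simulate_intensities(
            lib, probes, noise=(10, 50, 0.0), n_replicates=1
        ).values.mean()
    assert out["lo"] > out["hi"]
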
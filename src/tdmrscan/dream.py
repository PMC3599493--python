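"""In-silico methylation-sensitive restriction profiling.

Models the tag-amplification assay: HpyCH4IV (A^CGT) cuts a site only when
its CpG is unmethylated, TaqI (T^CGA) cuts regardless of methylation (it
acts after adaptor fill-in on purified DNA), distinct adaptors are ligated
to the two end chemistries, and only fragments carrying one HpyCH4IV end
and one TaqI end amplify (same-adaptor panhandle suppression). Probe
signal is therefore a readout of *unmethylated* HpyCH4IV sites.

Two digestion modes are provided: ``sampled`` draws a Bernoulli cut per
site per molecule, while ``deterministic_expected`` enumerates every
possible fragment with its expected copy number, giving a noise-free
readout for validation work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import (
    CONTIG_END,
    HPY_END,
    TAQ_END,
    FragmentLibrary,
    IntensityMatrix,
    MethylomeProfile,
    ProbeSet,
    RestrictionFragment,
)


@dataclass(frozen=True)
class Enzyme:
    name: str
    motif: str
    cut_offset: int
    methylation_sensitive: bool
    end_label: str


HPYCH4IV = Enzyme("HpyCH4IV", "ACGT", 1, True, HPY_END)
TAQI = Enzyme("TaqI", "TCGA", 1, False, TAQ_END)

_WEIGHT_FLOOR = 1e-12


def find_recognition_sites(sequence: str, motif: str) -> list[int]:
    """Sorted start positions of every (possibly overlapping) motif match."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    out: list[int] = []
    i = sequence.find(motif)
    while i >= 0:
        out.append(i)
        i = sequence.find(motif, i + 1)
    return out


def _cut_events(
    contig: str,
    sequence: str,
    methylome: MethylomeProfile,
    enzymes: Sequence[Enzyme],
) -> list[tuple[int, str, float]]:
    """(cut position, end label, cut probability) for every recognition site."""
    events = []
    for enz in enzymes:
        for s in find_recognition_sites(sequence, enz.motif):
            if enz.methylation_sensitive:
                # the site's CpG sits one base into the motif (aCGt)
                m = methylome.get(contig, s + 1)
                p_cut = 1.0 - m
            else:
                p_cut = 1.0
            if p_cut > 0.0:
                events.append((s + enz.cut_offset, enz.end_label, p_cut))
    events.sort(key=lambda ev: ev[0])
    return events


def digest(
    contig: str,
    sequence: str,
    methylome: MethylomeProfile,
    enzymes: Sequence[Enzyme] = (HPYCH4IV, TAQI),
    mode: str = "deterministic_expected",
    seed: int | None = None,
    weight_floor: float = _WEIGHT_FLOOR,
) -> tuple[list[RestrictionFragment], np.ndarray]:
    """Double-digest a contig, tracking per-fragment cut probabilities.

    In ``sampled`` mode each methylation-sensitive site is cut with
    probability (1 − methylated fraction); the realized fragments partition
    the contig exactly and all carry weight 1. In ``deterministic_expected``
    mode every fragment that could arise is returned with its expected copy
    number: P(cut left) × P(cut right) × Π P(uncut) over interior sites.
    Fragments with expected weight below ``weight_floor`` are dropped.
    """
    if mode not in ("deterministic_expected", "sampled"):
        raise ValueError(f"unknown digestion mode {mode!r}")
    events = _cut_events(contig, sequence, methylome, enzymes)
    L = len(sequence)
    bounds = [(0, CONTIG_END, 1.0)] + events + [(L, CONTIG_END, 1.0)]

    fragments: list[RestrictionFragment] = []
    weights: list[float] = []
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        cut = [True] + [rng.random() < p for _, _, p in events] + [True]
        prev = 0
        for idx in range(1, len(bounds)):
            if not cut[idx]:
                continue
            pos, label, _ = bounds[idx]
            ppos, plabel, _ = bounds[prev]
            if pos > ppos:
                fragments.append(RestrictionFragment(contig, ppos, pos, plabel, label))
                weights.append(1.0)
            prev = idx
        return fragments, np.asarray(weights)

    n = len(bounds)
    for i in range(n - 1):
        pos_i, label_i, p_i = bounds[i]
        w = p_i
        for j in range(i + 1, n):
            pos_j, label_j, p_j = bounds[j]
            wij = w * p_j
            if wij >= weight_floor and pos_j > pos_i:
                fragments.append(
                    RestrictionFragment(contig, pos_i, pos_j, label_i, label_j)
                )
                weights.append(wij)
            w *= 1.0 - p_j  # site j must stay uncut for any longer fragment
            if w < weight_floor:
                break
    return fragments, np.asarray(weights)


def select_amplifiable(
    fragments: Sequence[RestrictionFragment],
    weights: np.ndarray,
    size_range: tuple[int, int] = (40, 1000),
    sample_id: str = "",
) -> FragmentLibrary:
    """Keep fragments with exactly one HpyCH4IV and one TaqI end, in size range.

    Same-adaptor (HPY–HPY, TAQ–TAQ) and contig-end fragments do not amplify
    under the two-adaptor PCR and are dropped; weights carry through.
    """
    lo, hi = size_range
    if lo >= hi:
        raise ValueError(f"size_range min {lo} must be < max {hi}")
    weights = np.asarray(weights, dtype=float)
    kept_f, kept_w = [], []
    for frag, w in zip(fragments, weights):
        if {frag.left_end, frag.right_end} == {HPY_END, TAQ_END} and lo <= frag.length <= hi:
            kept_f.append(frag)
            kept_w.append(w)
    return FragmentLibrary(sample_id=sample_id, fragments=kept_f, weights=np.asarray(kept_w))


def build_probes(genes, step: int = 35, length: int = 25) -> ProbeSet:
    """Tile probes across every promoter window at a fixed step."""
    contigs, starts = [], []
    for gene in genes:
        s, e = gene.promoter_window
        pos = np.arange(s, e - length + 1, step, dtype=np.int64)
        starts.append(pos)
        contigs.extend([gene.contig] * len(pos))
    if not contigs:
        raise ValueError("no probes could be tiled (empty gene list?)")
    return ProbeSet(contig=np.array(contigs, dtype=object), start=np.concatenate(starts),
                    length=length, step=step)


def simulate_intensities(
    library: FragmentLibrary,
    probes: ProbeSet,
    noise: tuple[float, float, float] = (10.0, 50.0, 0.3),
    n_replicates: int = 2,
    seed: int | None = None,
) -> IntensityMatrix:
    """Hybridization readout: background + gain × fragment coverage, log-normal noise.

    probe intensity = (b + g · Σ weights of overlapping fragments) · exp(N(0, σ²)),
    drawn independently per probe and replicate; σ=0 gives a deterministic
    readout.
    """
    b, g, sigma = noise
    if b <= 0 or g <= 0:
        raise ValueError("background and gain must be positive")
    if sigma < 0:
        raise ValueError("noise sd must be non-negative")
    if n_replicates < 1:
        raise ValueError("at least one replicate required")
    if len(probes) == 0:
        raise ValueError("empty probe set")

    coverage = np.zeros(len(probes))
    by_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in np.unique(probes.contig.astype(str)):
        idx = np.flatnonzero(probes.contig.astype(str) == c)
        by_contig[c] = (idx, probes.start[idx])
    for frag, w in zip(library.fragments, library.weights):
        if frag.contig not in by_contig:
            continue
        idx, starts = by_contig[frag.contig]
        # probe [p, p+len) overlaps fragment iff p > frag.start - len and p < frag.end
        lo = np.searchsorted(starts, frag.start - probes.length + 1, side="left")
        hi = np.searchsorted(starts, frag.end, side="left")
        coverage[idx[lo:hi]] += w

    mu = b + g * coverage
    rng = np.random.default_rng(seed)
    if sigma == 0:
        values = np.repeat(mu[:, None], n_replicates, axis=1)
    else:
        values = mu[:, None] * np.exp(
            rng.normal(0.0, sigma, size=(len(probes), n_replicates))
        )
    return IntensityMatrix(probes=probes, values=values, sample_id=library.sample_id)


def digest_and_select(
    genome,
    methylome: MethylomeProfile,
    mode: str = "deterministic_expected",
    size_range: tuple[int, int] = (40, 1000),
    seed: int | None = None,
) -> FragmentLibrary:
    """Convenience: full-genome digestion plus amplifiable-fragment selection."""
    all_frags: list[RestrictionFragment] = []
    all_w: list[np.ndarray] = []
    for contig, seq in genome.contigs.items():
        frags, w = digest(contig, seq, methylome, mode=mode, seed=seed)
        all_frags.extend(frags)
        all_w.append(w)
    weights = np.concatenate(all_w) if all_w else np.empty(0)
    return select_amplifiable(all_frags, weights, size_range, sample_id=methylome.sample_id)
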
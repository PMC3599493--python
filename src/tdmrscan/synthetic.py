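"""Synthetic genomes, gene models, CGIs and methylomes with implanted T-DMRs.

The generator emulates the study design of a promoter-tiling,
methylation-sensitive restriction screen in mouse neural progenitors:

* one contig carrying non-overlapping promoter windows (6 kb upstream to
  2.5 kb downstream of each TSS),
* mouse-like CpG depletion in the background (obs/exp ≈ 0.2, which yields
  roughly 0.7 HpyCH4IV [ACGT] and TaqI [TCGA] sites per kb, as in the real
  genome) with CpG-island blocks at about half the TSSs,
* per-population methylation stored as a fraction per CpG site — cell
  subpopulation heterogeneity makes intermediate methylation levels the
  rule, not the exception,
* differential regions implanted at chosen promoter positions with a
  specified methylation difference, anchored on HpyCH4IV site clusters so
  every implanted region is assessable by the assay (a gene without a
  proximal HpyCH4IV site cannot be screened, so such regions are excluded
  by construction, mirroring the assay's own blind spots).

Identical seeds produce byte-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .types import (
    GeneModel,
    GenomeAssembly,
    Interval,
    MethylomeProfile,
    TruthTDMR,
    PROMOTER_SPAN,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3

#: strand-oriented promoter sub-regions used for implant placement, bp from TSS
POSITION_CLASSES: dict[str, tuple[int, int]] = {
    "proximal_5p": (-2000, 500),
    "distal_5p": (-6000, -2000),
    "downstream_3p": (500, 2500),
}

DEFAULT_SPACING = {
    "gap_min": 500,
    "gap_max": 1500,
    "margin": 200,
    "cgi_halfwidth": 500,
    "min_hpy_per_region": 2,
    "min_taq_per_region": 2,
    "bg_gc": 0.42,
    "bg_cpg_obs_exp": 0.2,
    "cgi_gc": 0.6,
    "cgi_cpg_obs_exp": 0.8,
    "require_readable_segment": True,
}

#: geometry of a "readable" TaqI-bounded segment (see _segment_candidates)
SEGMENT_PARAMS = {
    "min_len": 600,
    "max_len": 1800,
    "ideal_len": 1200,
    "max_mid_gap": 150,
    "min_readable_frac": 0.7,
    "max_dead_run": 300,
    "amplifiable_range": (40, 1000),
}

DEFAULT_BASELINE = {
    "cgi_alpha": 1.0,
    "cgi_beta": 9.0,
    "bg_alpha": 8.0,
    "bg_beta": 2.0,
    "hypo_level": 0.1,
}


@dataclass(frozen=True)
class ImplantSpec:
    """Request for one implanted T-DMR.

    ``direction`` is ``"hypo_in_<sample>"``; several samples may share the
    hypomethylated state via ``"hypo_in_B+AD"``.
    """

    gene_id: str
    position_class: str
    delta: float
    direction: str

    def hypo_samples(self) -> tuple[str, ...]:
        if not self.direction.startswith("hypo_in_"):
            raise ValueError(f"direction must start with 'hypo_in_', got {self.direction!r}")
        return tuple(self.direction[len("hypo_in_"):].split("+"))


def class_region(gene: GeneModel, position_class: str) -> tuple[int, int]:
    """Genomic half-open bounds of a strand-oriented promoter sub-region."""
    lo, hi = POSITION_CLASSES[position_class]
    if gene.strand == "+":
        return gene.tss + lo, gene.tss + hi
    return gene.tss - hi + 1, gene.tss - lo + 1


# ---------------------------------------------------------------------------
# sequence synthesis
# ---------------------------------------------------------------------------


def _segment(rng: np.random.Generator, length: int, gc: float, cpg_obs_exp: float) -> np.ndarray:
    """IID bases at the given GC content, CpG-thinned to a target obs/exp.

    Bases are drawn independently (so CpG obs/exp starts at 1), then each CG
    dinucleotide's G is mutated to A/T with probability ``1 - cpg_obs_exp``.
    The replacement can never create a new CG, so the thinning is exact to
    first order and single-pass.
    """
    if length <= 0:
        return np.empty(0, dtype=np.uint8)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    cg = np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G))
    drop = cg[rng.random(cg.size) > cpg_obs_exp]
    codes[drop + 1] = np.where(rng.random(drop.size) < 0.5, _A, _T).astype(np.uint8)
    return codes


def _count_motif(codes: np.ndarray, motif: Sequence[int], start: int, end: int) -> int:
    """Occurrences of a 4-mer whose start lies in [start, end)."""
    end = min(end, len(codes) - len(motif) + 1)
    if end <= start:
        return 0
    window = codes[start : end + len(motif) - 1]
    hit = np.ones(end - start, dtype=bool)
    for k, b in enumerate(motif):
        hit &= window[k : k + end - start] == b
    return int(hit.sum())


_HPY_MOTIF = (_A, _C, _G, _T)
_TAQ_MOTIF = (_T, _C, _G, _A)


def generate_genome(
    n_genes: int,
    contig_length: int | None = None,
    cgi_fraction: float = 0.5,
    spacing_params: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[GenomeAssembly, list[GeneModel], list[Interval]]:
    """Build one contig with tiled, non-overlapping promoter windows.

    Returns the assembly, the gene models (TSS, strand, promoter window) and
    the list of implanted CGI blocks. A fraction ``cgi_fraction`` of genes
    (independent Bernoulli draws) get a CpG-island block centred on the TSS
    that satisfies the Gardiner-Garden–Frommer criteria; the remainder keep
    CpG-depleted background across the promoter. Every promoter sub-region
    (proximal/distal/downstream) is resampled until it carries a minimum
    number of HpyCH4IV and TaqI sites, so every gene is assessable by the
    restriction assay.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1 (empty design rejected)")
    if not (0.0 <= cgi_fraction <= 1.0):
        raise ValueError("cgi_fraction must lie in [0, 1]")
    sp = dict(DEFAULT_SPACING)
    if spacing_params:
        sp.update(spacing_params)
    rng = np.random.default_rng(seed)

    margin = int(sp["margin"])
    gaps = rng.integers(int(sp["gap_min"]), int(sp["gap_max"]) + 1, size=n_genes + 1)
    gaps[0] += margin
    gaps[-1] += margin
    required = int(gaps.sum()) + n_genes * PROMOTER_SPAN
    if contig_length is None:
        contig_length = required
    elif contig_length < required:
        raise ValueError(
            f"contig_length {contig_length} cannot hold {n_genes} promoter windows "
            f"plus spacing (needs >= {required})"
        )

    # lay out genes left to right
    genes: list[GeneModel] = []
    is_cgi = rng.random(n_genes) < cgi_fraction
    cursor = 0
    width = len(str(n_genes - 1))
    for i in range(n_genes):
        cursor += int(gaps[i])
        wstart = cursor
        strand = "+" if rng.random() < 0.5 else "-"
        # place the TSS so the strand-oriented window is exactly [wstart, wstart+8500)
        tss = wstart + 6000 if strand == "+" else wstart + 2499
        gene = GeneModel(gene_id=f"gene_{i:0{width}d}", contig="chr1", tss=tss, strand=strand)
        assert gene.promoter_window == (wstart, wstart + PROMOTER_SPAN)
        genes.append(gene)
        cursor += PROMOTER_SPAN

    codes = _segment(rng, contig_length, sp["bg_gc"], sp["bg_cpg_obs_exp"])
    cgis: list[Interval] = []
    half = int(sp["cgi_halfwidth"])
    for gene, flag in zip(genes, is_cgi):
        if not flag:
            continue
        s, e = gene.tss - half, gene.tss + half
        codes[s:e] = _segment(rng, e - s, sp["cgi_gc"], sp["cgi_cpg_obs_exp"])
        cgis.append(Interval("chr1", s, e))

    # guarantee restriction-site coverage in every promoter sub-region
    cgi_by_gene = {}
    for gene, flag in zip(genes, is_cgi):
        if flag:
            cgi_by_gene[gene.gene_id] = (gene.tss - half, gene.tss + half)
    min_hpy = int(sp["min_hpy_per_region"])
    min_taq = int(sp["min_taq_per_region"])
    need_readable = bool(sp["require_readable_segment"])

    def _region_ok(rs: int, re_: int) -> bool:
        if (
            _count_motif(codes, _HPY_MOTIF, rs, re_) < min_hpy
            or _count_motif(codes, _TAQ_MOTIF, rs, re_) < min_taq
        ):
            return False
        if not need_readable:
            return True
        region_seq = _BASES[codes[rs:re_]].tobytes().decode("ascii")
        return has_readable_segment(region_seq, 0, re_ - rs)

    for _ in range(1000):
        dirty = False
        for gene in genes:
            for cls in POSITION_CLASSES:
                rs, re_ = class_region(gene, cls)
                for _try in range(5000):
                    if _region_ok(rs, re_):
                        break
                    dirty = True
                    codes[rs:re_] = _segment(
                        rng, re_ - rs, sp["bg_gc"], sp["bg_cpg_obs_exp"]
                    )
                    if gene.gene_id in cgi_by_gene:
                        cs, ce = cgi_by_gene[gene.gene_id]
                        os_, oe = max(cs, rs), min(ce, re_)
                        if os_ < oe:
                            codes[os_:oe] = _segment(
                                rng, oe - os_, sp["cgi_gc"], sp["cgi_cpg_obs_exp"]
                            )
                else:
                    raise RuntimeError(
                        f"could not satisfy restriction-site minimum in {gene.gene_id} {cls}"
                    )
        if not dirty:
            break

    seq = _BASES[codes].tobytes().decode("ascii")
    return GenomeAssembly({"chr1": seq}), genes, cgis


# ---------------------------------------------------------------------------
# methylomes
# ---------------------------------------------------------------------------


def cpg_positions(sequence: str) -> np.ndarray:
    """Positions of the C of every CpG dinucleotide (top strand)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)


def _find_motif_starts(sequence: str, motif: str, start: int, end: int) -> list[int]:
    out = []
    i = sequence.find(motif, start)
    while 0 <= i < end:
        out.append(i)
        i = sequence.find(motif, i + 1)
    return out


def _cut_layout(seq: str, lo: int, hi: int) -> list[tuple[int, str]]:
    """Sorted (cut position, enzyme) pairs for both enzymes within [lo, hi)."""
    cuts = [(h + 1, "H") for h in _find_motif_starts(seq, "ACGT", lo, hi)]
    cuts += [(t + 1, "T") for t in _find_motif_starts(seq, "TCGA", lo, hi)]
    cuts.sort()
    return cuts


def _segment_candidates(
    seq: str, rs: int, re_: int, params: Mapping | None = None
) -> list[tuple[tuple, int, int]]:
    """Ranked TaqI-bounded implant candidates within a promoter sub-region.

    Fragments of the double digestion never cross a TaqI cut, so an
    interval spanning adjacent TaqI cuts confines the differential
    fragment footprint of any methylation change to the interval itself.
    The readout contrast of such a segment depends sharply on its internal
    HpyCH4IV layout: with exactly one internal cut (T·H·T) the segment
    reads out the site's methylation uniformly over its whole length
    (hypomethylated coverage ≈ cut probability vs. the suppressed TaqI–TaqI
    span on the other side), whereas runs of several internal sites create
    adaptor-suppressed HpyCH4IV–HpyCH4IV stretches whose signal *inverts*.
    Candidates are therefore tiered:

    0. one internal HpyCH4IV cut, both halves amplifiable;
    1. two internal cuts less than ``max_mid_gap`` apart (the inverted
       middle stretch is short enough for the windowed score to bridge);
    2. any layout with readable fraction ≥ ``min_readable_frac`` and no
       dead run over ``max_dead_run``;
    3. the rest.

    Within a tier, candidates closest to ``ideal_len`` rank first.
    Returns (key, start, end) sorted best-first.
    """
    sp = dict(SEGMENT_PARAMS)
    if params:
        sp.update(params)
    frag_lo, frag_hi = sp["amplifiable_range"]
    cuts = _cut_layout(seq, rs, re_)
    taq_idx = [i for i, (_, kind) in enumerate(cuts) if kind == "T"]
    out = []
    for ai, bi in zip(taq_idx[:-1], taq_idx[1:]):  # adjacent TaqI cuts only
        a, b = cuts[ai][0], cuts[bi][0]
        length = b - a
        if not (sp["min_len"] <= length <= sp["max_len"]):
            continue
        hpy = [p for p, kind in cuts[ai + 1 : bi] if kind == "H"]
        if not hpy:
            continue
        gaps = np.diff([a] + hpy + [b])
        amplifiable = (gaps >= frag_lo) & (gaps <= frag_hi)
        if len(hpy) == 1 and amplifiable.all():
            tier = 0
        elif (
            len(hpy) == 2
            and amplifiable[0]
            and amplifiable[-1]
            and gaps[1] <= sp["max_mid_gap"]
        ):
            tier = 1
        else:
            readable = int(gaps[0] * amplifiable[0] + gaps[-1] * amplifiable[-1])
            interior_dead = int(gaps[1:-1].sum()) if len(gaps) > 2 else 0
            frac = readable / length
            ok = frac >= sp["min_readable_frac"] and interior_dead <= sp["max_dead_run"]
            tier = 2 if ok else 3
        key = (tier, abs(length - sp["ideal_len"]))
        out.append((key, a, b))
    out.sort(key=lambda c: c[0])
    return out


def has_readable_segment(seq: str, rs: int, re_: int, params: Mapping | None = None) -> bool:
    """True when the region holds a tier-0 implant candidate (T·H·T layout)."""
    cands = _segment_candidates(seq, rs, re_, params)
    return bool(cands) and cands[0][0][0] == 0


def _place_implant(
    seq: str,
    rs: int,
    re_: int,
    hpy_sites: list[int],
    bp: Mapping[str, float],
) -> tuple[int, int]:
    """Best implant interval for a region: TaqI-bounded if possible.

    Falls back to the padded span of the densest HpyCH4IV cluster when the
    region offers no TaqI-bounded candidate at all.
    """
    cands = _segment_candidates(seq, rs, re_)
    if cands:
        _, a, b = cands[0]
        return a, b

    pad = 100
    span = SEGMENT_PARAMS["max_len"] - 2 * pad
    pick = (0, 0)
    j = 0
    for i in range(len(hpy_sites)):
        if j < i:
            j = i
        while j + 1 < len(hpy_sites) and hpy_sites[j + 1] + 4 - hpy_sites[i] <= span:
            j += 1
        if j - i + 1 > pick[0]:
            pick = (j - i + 1, i)
    i = pick[1]
    j = i
    while j + 1 < len(hpy_sites) and hpy_sites[j + 1] + 4 - hpy_sites[i] <= span:
        j += 1
    return max(rs, hpy_sites[i] - pad), min(re_, hpy_sites[j] + 4 + pad)


def generate_methylomes(
    genome: GenomeAssembly,
    genes: Sequence[GeneModel],
    tdmr_spec: Sequence[ImplantSpec | tuple],
    baseline_params: Mapping[str, float] | None = None,
    seed: int = 0,
    sample_ids: Sequence[str] = ("A", "B"),
    cgis: Sequence[Interval] = (),
) -> tuple[list[MethylomeProfile], list[TruthTDMR]]:
    """Draw per-CpG methylomes for each sample and implant T-DMRs.

    Baseline methylation is drawn once and shared by all samples: CpGs inside
    a CGI block follow Beta(cgi_alpha, cgi_beta) (low — CGIs are normally
    unmethylated), everything else Beta(bg_alpha, bg_beta) (high). Each
    implant overwrites the CpGs of a HpyCH4IV-anchored interval inside the
    requested promoter sub-region: the hypomethylated sample(s) get
    ``hypo_level`` and every other sample ``hypo_level + delta`` (clipped to
    1 with a warning if delta pushes past it), so the realized between-sample
    difference equals the requested delta exactly.
    """
    bp = dict(DEFAULT_BASELINE)
    if baseline_params:
        bp.update(baseline_params)
    rng = np.random.default_rng(seed)
    sample_ids = list(sample_ids)
    genes_by_id = {g.gene_id: g for g in genes}
    spec = [s if isinstance(s, ImplantSpec) else ImplantSpec(*s) for s in tdmr_spec]
    for item in spec:
        if item.gene_id not in genes_by_id:
            raise KeyError(f"implant references unknown gene {item.gene_id!r}")
        if item.position_class not in POSITION_CLASSES:
            raise ValueError(f"unknown position class {item.position_class!r}")
        for sid in item.hypo_samples():
            if sid not in sample_ids:
                raise ValueError(f"direction {item.direction!r} names unknown sample {sid!r}")

    profiles = {sid: {} for sid in sample_ids}
    truths: list[TruthTDMR] = []
    for contig, seq in genome.contigs.items():
        pos = cpg_positions(seq)
        in_cgi = np.zeros(pos.size, dtype=bool)
        for iv in cgis:
            if iv.contig == contig:
                in_cgi |= (pos >= iv.start) & (pos < iv.end)
        base = np.where(
            in_cgi,
            rng.beta(bp["cgi_alpha"], bp["cgi_beta"], size=pos.size),
            rng.beta(bp["bg_alpha"], bp["bg_beta"], size=pos.size),
        )
        for sid in sample_ids:
            profiles[sid][contig] = dict(zip(pos.tolist(), base.tolist()))

    for item in spec:
        gene = genes_by_id[item.gene_id]
        seq = genome[gene.contig]
        rs, re_ = class_region(gene, item.position_class)
        sites = _find_motif_starts(seq, "ACGT", rs, re_)
        if not sites:
            raise ValueError(
                f"no HpyCH4IV site in {item.position_class} of {item.gene_id}; "
                "region is not assessable"
            )
        start, end = _place_implant(seq, rs, re_, sites, bp)

        hypo = set(item.hypo_samples())
        hypo_level = float(bp["hypo_level"])
        hyper_level = hypo_level + float(item.delta)
        if hyper_level > 1.0:
            warnings.warn(
                f"implant delta {item.delta} pushes methylation above 1 in "
                f"{item.gene_id}; clipping to 1.0",
                stacklevel=2,
            )
            hyper_level = 1.0
        sites_here = [
            p for p in profiles[sample_ids[0]][gene.contig] if start <= p < end
        ]
        for p in sites_here:
            for sid in sample_ids:
                profiles[sid][gene.contig][p] = hypo_level if sid in hypo else hyper_level
        realized = hyper_level - hypo_level
        a, b = sample_ids[0], sample_ids[1] if len(sample_ids) > 1 else sample_ids[0]
        if a in hypo and b not in hypo:
            signed = -realized
        elif b in hypo and a not in hypo:
            signed = realized
        else:
            signed = -realized  # hypo sample(s) outside the primary pair
        truths.append(
            TruthTDMR(
                contig=gene.contig,
                start=start,
                end=end,
                direction=item.direction,
                delta_methylation=signed,
                gene_id=item.gene_id,
                position_class=item.position_class,
            )
        )

    out = [MethylomeProfile(sid, profiles[sid]) for sid in sample_ids]
    return out, truths


# ---------------------------------------------------------------------------
# truth table IO
# ---------------------------------------------------------------------------

_TRUTH_HEADER = "#contig\tstart\tend\tgene_id\tdelta_methylation\tdirection\tposition_class"


def write_truth(truths: Sequence[TruthTDMR], path: str) -> None:
    """BED-with-extra-columns truth table (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for t in truths:
            fh.write(
                f"{t.contig}\t{t.start}\t{t.end}\t{t.gene_id}\t"
                f"{t.delta_methylation:.6g}\t{t.direction}\t{t.position_class}\n"
            )


def read_truth(path: str) -> list[TruthTDMR]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            c, s, e, g, d, direc, cls = fields
            out.append(
                TruthTDMR(c, int(s), int(e), direc, float(d), g, cls)
            )
    return out


# ---------------------------------------------------------------------------
# cluster archetypes
# ---------------------------------------------------------------------------

#: ΔMATscore archetype profiles over (adult rep1, adult rep2, other-NSph rep1,
#: other-NSph rep2), each Δ taken against the direction-specific control stage.
PROFILE_ARCHETYPES: dict[str, tuple[float, float, float, float]] = {
    "hypo_in_both": (4.0, 4.0, 4.0, 4.0),
    "hypo_in_adult_only": (4.0, 4.0, 0.0, 0.0),
    "hyper_in_adult": (-4.0, -4.0, 0.0, 0.0),
}

PROFILE_COLUMNS = ("AdBr_rep1", "AdBr_rep2", "NSph_rep1", "NSph_rep2")


def make_profile_archetypes(
    n_rows: int = 200, noise_sd: float = 0.3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Rows drawn round-robin from the three archetypes plus Gaussian noise.

    Returns (matrix of shape n_rows × 4, integer archetype labels).
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    protos = np.array(list(PROFILE_ARCHETYPES.values()))
    labels = np.arange(n_rows) % len(protos)
    matrix = protos[labels] + rng.normal(0.0, noise_sd, size=(n_rows, protos.shape[1]))
    return matrix, labels
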
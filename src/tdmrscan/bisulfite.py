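"""In-silico bisulfite conversion, clone sequencing, and COBRA.

Bisulfite chemistry converts unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine is retained; only the top strand is
modeled, since bisulfite PCR primers are strand-specific. COBRA digests
the bisulfite PCR product with HpyCH4IV — a site survives conversion only
if its CpG was methylated — and quantifies the cut/uncut band intensities
densitometrically (stain intensity proportional to fragment length).
"""

from __future__ import annotations

from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .types import (
    BisulfiteClone,
    CobraResult,
    Interval,
    METHYLATED,
    MethylomeProfile,
    UNDETERMINED,
    UNMETHYLATED,
)
from .synthetic import cpg_positions


def bisulfite_convert(
    sequence: str,
    cpg_methyl_calls: Mapping[int, str],
    non_conversion_rate: float = 0.0,
    seed: int | None = None,
) -> str:
    """Top-strand bisulfite conversion of a sequence given per-CpG calls.

    Every cytosine outside CpG context becomes T. A CpG cytosine is retained
    iff its call is methylated. With ``non_conversion_rate`` r > 0, each
    unmethylated C (CpG or not) independently escapes conversion with
    probability r, modeling incomplete chemistry. Output is in PCR sense
    (uracil rendered as T).
    """
    if not (0.0 <= non_conversion_rate <= 1.0):
        raise ValueError("non_conversion_rate must lie in [0, 1]")
    cpg_here = set(cpg_positions(sequence).tolist())
    for pos in cpg_methyl_calls:
        if pos not in cpg_here:
            raise ValueError(f"methylation call at position {pos} is not a CpG site")
    missing = cpg_here - set(cpg_methyl_calls)
    if missing:
        raise ValueError(f"CpG sites without a call: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    out = list(sequence)
    for i, base in enumerate(sequence):
        if base != "C":
            continue
        if i in cpg_here and cpg_methyl_calls[i] == METHYLATED:
            continue  # 5mC is retained
        if non_conversion_rate > 0 and rng.random() < non_conversion_rate:
            continue  # escaped conversion
        out[i] = "T"
    return "".join(out)


def simulate_clones(
    region: Interval,
    region_sequence: str,
    methylome: MethylomeProfile,
    n_clones: int = 16,
    undetermined_rate: float = 0.0,
    seed: int | None = None,
) -> list[BisulfiteClone]:
    """Simulate bisulfite clone sequencing of one region.

    Each clone is an independent molecule: every CpG draws a binary
    methylation state Bernoulli(population fraction), the molecule is
    bisulfite-converted, and each call is masked to undetermined with
    probability ``undetermined_rate`` (unreadable trace positions).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if len(region_sequence) != region.length:
        raise ValueError("region_sequence length must match the region")
    rng = np.random.default_rng(seed)
    local_cpgs = cpg_positions(region_sequence)
    fracs = np.array(
        [methylome.get(region.contig, region.start + int(p)) for p in local_cpgs]
    )
    clones = []
    for _ in range(n_clones):
        states = rng.random(local_cpgs.size) < fracs
        calls = {
            int(p): (METHYLATED if s else UNMETHYLATED)
            for p, s in zip(local_cpgs, states)
        }
        seq = bisulfite_convert(region_sequence, calls, seed=int(rng.integers(2**31)))
        masked = {
            p: (UNDETERMINED if rng.random() < undetermined_rate else c)
            for p, c in calls.items()
        }
        clones.append(BisulfiteClone(region=region, sequence=seq, calls=masked))
    return clones


def summarize_clones(
    clones: Sequence[BisulfiteClone],
) -> tuple[dict[int, float | None], float | None]:
    """Per-CpG and overall percent methylation, excluding undetermined calls.

    A site with zero determinate calls reports None (missing).
    """
    if not clones:
        raise ValueError("no clones to summarize")
    positions = sorted(clones[0].calls)
    per_site: dict[int, float | None] = {}
    total_m = total = 0
    for p in positions:
        m = sum(1 for c in clones if c.calls[p] == METHYLATED)
        u = sum(1 for c in clones if c.calls[p] == UNMETHYLATED)
        per_site[p] = 100.0 * m / (m + u) if (m + u) else None
        total_m += m
        total += m + u
    overall = 100.0 * total_m / total if total else None
    return per_site, overall


def cobra(
    region: Interval,
    site_positions: Sequence[int],
    molecule_population: Mapping[tuple[bool, ...], float],
    primer_span: tuple[int, int],
) -> CobraResult:
    """COBRA digestion of a bisulfite amplicon and densitometric readout.

    ``molecule_population`` maps per-site methylation patterns (True =
    methylated, one flag per assayed HpyCH4IV site) to molecule counts.
    After bisulfite PCR, a site's ACGT sequence survives — and is cut at
    offset 1 — iff that molecule's CpG was methylated. Band intensity for
    each fragment length is Σ molecule count × fragment length (ethidium
    staining scales with mass). The methylation percentage is the
    cut-derived share of total band intensity; for a single site this is
    exactly 100 × methylated molecules / total.
    """
    lo, hi = primer_span
    if lo >= hi:
        raise ValueError("primer_span must be a non-empty interval")
    sites = sorted(int(s) for s in site_positions)
    if not sites:
        raise ValueError("no restriction sites inside the primer span")
    for s in sites:
        if not (lo <= s and s + 4 <= hi):
            raise ValueError(f"site at {s} lies outside the primer span {primer_span}")
    total_molecules = float(sum(molecule_population.values()))
    if total_molecules <= 0 or any(v < 0 for v in molecule_population.values()):
        raise ValueError("molecule counts must be non-negative with positive total")

    band_weights: dict[int, float] = {}
    cut_intensity = 0.0
    total_intensity = 0.0
    for pattern, count in molecule_population.items():
        if len(pattern) != len(sites):
            raise ValueError("pattern length must match the number of sites")
        if count == 0:
            continue
        cuts = [s + 1 for s, methylated in zip(sites, pattern) if methylated]
        edges = [lo] + cuts + [hi]
        for a, b in zip(edges[:-1], edges[1:]):
            length = b - a
            w = count * length
            band_weights[length] = band_weights.get(length, 0.0) + w
            total_intensity += w
            if cuts:  # every band of a cut molecule derives from digestion
                cut_intensity += w
    percent = 100.0 * cut_intensity / total_intensity
    return CobraResult(
        region=region,
        site_positions=tuple(sites),
        band_weights=band_weights,
        methylation_percent=percent,
    )


def cobra_from_methylome(
    region: Interval,
    region_sequence: str,
    methylome: MethylomeProfile,
    primer_span: tuple[int, int] | None = None,
    n_molecules: float = 1000.0,
) -> CobraResult:
    """Deterministic COBRA driven by population methylation fractions.

    Builds the expected molecule population over all cut patterns of the
    region's HpyCH4IV sites (independent sites) and runs :func:`cobra`.
    """
    if primer_span is None:
        primer_span = (0, region.length)
    starts = []
    i = region_sequence.find("ACGT")
    while i >= 0:
        starts.append(i)
        i = region_sequence.find("ACGT", i + 1)
    sites = [s for s in starts if primer_span[0] <= s and s + 4 <= primer_span[1]]
    if not sites:
        raise ValueError("region has no HpyCH4IV site inside the primer span")
    fracs = [methylome.get(region.contig, region.start + s + 1) for s in sites]
    population = {}
    for pattern in product((False, True), repeat=len(sites)):
        p = 1.0
        for meth, f in zip(pattern, fracs):
            p *= f if meth else (1.0 - f)
        population[pattern] = n_molecules * p
    return cobra(region, sites, population, primer_span)
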
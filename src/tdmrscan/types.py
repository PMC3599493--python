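"""Domain containers shared across the pipeline.

Coordinate conventions
----------------------
All genomic intervals are 0-based, half-open ``[start, end)``. A CpG site is
indexed by the position of its C on the + strand. Strand-oriented offsets
(e.g. distance from a TSS) are positive downstream of the TSS in the gene's
reading direction and negative upstream; they are computed only at reporting
boundaries, never stored as alternative coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

PROMOTER_UPSTREAM = 6000
PROMOTER_DOWNSTREAM = 2500
PROMOTER_SPAN = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM

_ALPHABET = frozenset("ACGT")


def promoter_bounds(tss: int, strand: str) -> tuple[int, int]:
    """Genomic half-open bounds of the promoter window around a TSS.

    The window runs from 6 kb upstream to 2.5 kb downstream of the TSS in
    strand-oriented coordinates; on the − strand this flips genomically.
    """
    if strand == "+":
        return tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    if strand == "-":
        # oriented offset o = tss - x in [-6000, 2500)  <=>  x in (tss-2500, tss+6000]
        return tss - PROMOTER_DOWNSTREAM + 1, tss + PROMOTER_UPSTREAM + 1
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def oriented_offset(tss: int, strand: str, pos: int) -> int:
    """Strand-oriented signed offset of a genomic position from the TSS."""
    return pos - tss if strand == "+" else tss - pos


@dataclass
class GenomeAssembly:
    """A set of named contigs over the {A,C,G,T} alphabet."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("GenomeAssembly requires at least one contig")
        for name, seq in self.contigs.items():
            if len(seq) < 1:
                raise ValueError(f"contig {name!r} is empty")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"contig {name!r} contains non-ACGT characters: {sorted(bad)}")

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]


@dataclass(frozen=True)
class GeneModel:
    """A gene TSS with its strand-oriented promoter window."""

    gene_id: str
    contig: str
    tss: int
    strand: str
    promoter_window: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.promoter_window is None:
            object.__setattr__(self, "promoter_window", promoter_bounds(self.tss, self.strand))

    def offset(self, pos: int) -> int:
        return oriented_offset(self.tss, self.strand, pos)

    def contains(self, pos: int) -> bool:
        s, e = self.promoter_window
        return s <= pos < e


@dataclass(frozen=True)
class Interval:
    """A plain genomic interval (used for CGIs and similar annotations)."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MethylomeProfile:
    """Population-level methylated fraction per CpG site, per sample.

    Methylation is stored as a fraction in [0, 1] rather than a binary
    state: methylation changes in a mixed cell population are partial, and
    the restriction assay reads out exactly this fraction (the probability
    that a given molecule's site is cleavable).
    """

    sample_id: str
    site_methylation: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        for contig, sites in self.site_methylation.items():
            for pos, frac in sites.items():
                if not (0.0 <= frac <= 1.0):
                    raise ValueError(
                        f"methylation fraction {frac} at {contig}:{pos} outside [0, 1]"
                    )

    def get(self, contig: str, pos: int) -> float:
        try:
            return self.site_methylation[contig][pos]
        except KeyError:
            raise KeyError(f"no methylation entry for CpG at {contig}:{pos}") from None

    def positions(self, contig: str) -> np.ndarray:
        return np.array(sorted(self.site_methylation.get(contig, {})), dtype=np.int64)

    def mean_over(self, contig: str, start: int, end: int) -> float:
        sites = self.site_methylation.get(contig, {})
        vals = [v for p, v in sites.items() if start <= p < end]
        if not vals:
            raise ValueError(f"no CpG sites in {contig}:[{start}, {end})")
        return float(np.mean(vals))


@dataclass(frozen=True)
class TruthTDMR:
    """Ground-truth implanted differentially methylated region."""

    contig: str
    start: int
    end: int
    direction: str  # "hypo_in_<sample>"
    delta_methylation: float
    gene_id: str
    position_class: str  # proximal_5p | distal_5p | downstream_3p

    def __post_init__(self) -> None:
        if abs(self.delta_methylation) <= 0:
            raise ValueError("delta_methylation must be non-zero")
        if self.start >= self.end:
            raise ValueError("empty truth interval")


# ---------------------------------------------------------------------------
# Assay readout containers
# ---------------------------------------------------------------------------

HPY_END = "HPY"
TAQ_END = "TAQ"
CONTIG_END = "CONTIG_END"


@dataclass(frozen=True)
class RestrictionFragment:
    contig: str
    start: int
    end: int
    left_end: str
    right_end: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must precede end")
        for lab in (self.left_end, self.right_end):
            if lab not in (HPY_END, TAQ_END, CONTIG_END):
                raise ValueError(f"unknown fragment end label {lab!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class FragmentLibrary:
    """Amplifiable fragments with expected molecule weights.

    The weight of a fragment is the expected number of molecule copies per
    genome equivalent: the probability that its bounding HpyCH4IV site was
    unmethylated (hence cut) times the probability that no internal site cut.
    """

    sample_id: str
    fragments: list[RestrictionFragment]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.fragments) != len(self.weights):
            raise ValueError("fragments and weights length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("fragment weights must be non-negative")
        for frag in self.fragments:
            ends = {frag.left_end, frag.right_end}
            if ends != {HPY_END, TAQ_END}:
                raise ValueError(
                    f"library fragment must have one HPY and one TAQ end, got {ends}"
                )


@dataclass
class ProbeSet:
    """Tiled 25-mer probes restricted to promoter windows."""

    contig: np.ndarray
    start: np.ndarray
    length: int = 25
    step: int = 35

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        if len(self.contig) != len(self.start):
            raise ValueError("contig and start arrays must align")
        order = np.lexsort((self.start, self.contig.astype(str)))
        self.contig = self.contig[order]
        self.start = self.start[order]

    def __len__(self) -> int:
        return len(self.start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"contig": self.contig, "start": self.start, "length": self.length})


@dataclass
class IntensityMatrix:
    """Probes × replicates table of strictly positive hybridization signals."""

    probes: ProbeSet
    values: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.probes):
            raise ValueError("values must be a probes × replicates matrix")
        if self.values.shape[1] < 1:
            raise ValueError("at least one replicate required")
        if np.any(self.values <= 0):
            raise ValueError("intensities must be strictly positive")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------


@dataclass
class ScoreTrack:
    """Windowed trimmed-mean scores at probe positions for one replicate."""

    sample_id: str
    records: pd.DataFrame  # columns: contig, position, score
    bandwidth: int
    trim: float
    min_probes: int

    def __post_init__(self) -> None:
        required = {"contig", "position", "score"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"ScoreTrack records need columns {sorted(required)}")
        self.records = (
            self.records.sort_values(["contig", "position"]).reset_index(drop=True)
        )


@dataclass
class DeltaTrack:
    """Between-condition score differences on shared probe positions.

    Positive delta means more assay signal — i.e. hypomethylation — in the
    test sample relative to the control.
    """

    test_sample: str
    control_sample: str
    records: pd.DataFrame  # columns: contig, position, delta

    def __post_init__(self) -> None:
        required = {"contig", "position", "delta"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"DeltaTrack records need columns {sorted(required)}")
        self.records = (
            self.records.sort_values(["contig", "position"]).reset_index(drop=True)
        )


@dataclass
class TDMR:
    """A called tissue-dependent differentially methylated region."""

    contig: str
    start: int
    end: int
    direction: str  # hypo_in_test | hypo_in_control
    mean_delta: float
    n_probes: int
    gene_id: str | None = None
    tss_distance: int | None = None
    cluster: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty T-DMR interval")
        if self.direction not in ("hypo_in_test", "hypo_in_control"):
            raise ValueError(f"unknown direction {self.direction!r}")
        expected_sign = 1.0 if self.direction == "hypo_in_test" else -1.0
        if self.mean_delta * expected_sign <= 0:
            raise ValueError("mean_delta sign inconsistent with direction")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# Profile / enrichment / bisulfite containers
# ---------------------------------------------------------------------------


@dataclass
class DistanceHistogram:
    """TSS-distance distribution in fixed 250-bp bins from −6 kb to +2.5 kb."""

    edges: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.proportions = np.asarray(self.proportions, dtype=float)
        widths = np.diff(self.edges)
        if not np.allclose(widths, 250):
            raise ValueError("histogram bin width must be exactly 250 bp")
        if len(self.proportions) != len(self.edges) - 1:
            raise ValueError("proportions must have one entry per bin")
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("histogram proportions must sum to 1")

    def mass_between(self, lo: float, hi: float) -> float:
        """Total proportion in bins fully inside [lo, hi]."""
        sel = (self.edges[:-1] >= lo) & (self.edges[1:] <= hi)
        return float(self.proportions[sel].sum())


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("overlap exceeds term or query size")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p outside [0, 1]")
        if self.q < self.p - 1e-12:
            raise ValueError("BH-adjusted q cannot be below p")


METHYLATED = "M"
UNMETHYLATED = "U"
UNDETERMINED = "N"


@dataclass
class BisulfiteClone:
    """One sequenced bisulfite clone of a region."""

    region: Interval
    sequence: str
    calls: dict[int, str]  # CpG position -> M/U/N

    def __post_init__(self) -> None:
        if len(self.sequence) != self.region.length:
            raise ValueError("converted sequence length must equal region length")
        for pos, call in self.calls.items():
            if call not in (METHYLATED, UNMETHYLATED, UNDETERMINED):
                raise ValueError(f"unknown call {call!r} at {pos}")


@dataclass
class CobraResult:
    """Densitometric COBRA readout for one amplicon."""

    region: Interval
    site_positions: tuple[int, ...]
    band_weights: dict[int, float]  # fragment length -> intensity
    methylation_percent: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.methylation_percent <= 100.0):
            raise ValueError("methylation percent outside [0, 100]")
        if any(w < 0 for w in self.band_weights.values()):
            raise ValueError("band intensities must be non-negative")


def as_intervals(records: Iterable[tuple[str, int, int]]) -> list[Interval]:
    return [Interval(c, s, e) for c, s, e in records]
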
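"""Model/Results surface for differential-methylation analysis.

:class:`DifferentialMethylation` is built from the two conditions' probe
intensity matrices; :meth:`~DifferentialMethylation.fit` standardizes,
scores, differences and segments them, returning a
:class:`DifferentialMethylationResults` holding the called T-DMRs with
per-call effect sizes and probe support, direction/gene tallies, and a
``summary()`` table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import calling, profiles, scoring
from .types import DeltaTrack, GeneModel, IntensityMatrix, ScoreTrack, TDMR


class DifferentialMethylation:
    """Windowed trimmed-mean differential scoring of two tiling-array conditions.

    Parameters
    ----------
    test, control
        Intensity matrices (probes × replicates) for the two conditions,
        sharing one probe set. Positive ΔMATscore marks hypomethylation in
        ``test``.
    genes
        Optional gene models for promoter-window assignment of calls.
    bandwidth_bp, trim_fraction, min_probes
        Scoring-window parameters: probes within ±bandwidth/2 are pooled,
        ``trim_fraction`` is dropped from each tail, and windows with fewer
        than ``min_probes`` probes emit no score.
    """

    def __init__(
        self,
        test: IntensityMatrix,
        control: IntensityMatrix,
        genes: Sequence[GeneModel] | None = None,
        bandwidth_bp: int = 500,
        trim_fraction: float = 0.1,
        min_probes: int = 4,
    ) -> None:
        if len(test.probes) != len(control.probes) or not np.array_equal(
            test.probes.start, control.probes.start
        ):
            raise ValueError("test and control must share one probe set")
        self.test = test
        self.control = control
        self.genes = list(genes) if genes else None
        self.bandwidth_bp = bandwidth_bp
        self.trim_fraction = trim_fraction
        self.min_probes = min_probes

    def score_tracks(self) -> dict[str, list[ScoreTrack]]:
        """Per-replicate score tracks for both conditions."""
        out = {}
        for im in (self.test, self.control):
            z = scoring.standardize(im)
            out[im.sample_id] = scoring.mat_score(
                z,
                im.probes,
                bandwidth_bp=self.bandwidth_bp,
                trim_fraction=self.trim_fraction,
                min_probes=self.min_probes,
                sample_id=im.sample_id,
            )
        return out

    def fit(
        self,
        threshold: float = 2.0,
        min_probes_run: int = 4,
        max_gap_bp: int = 300,
    ) -> "DifferentialMethylationResults":
        """Score both conditions, difference them, and segment T-DMRs."""
        tracks = self.score_tracks()
        combined = {
            sid: scoring.combine_replicates(reps) for sid, reps in tracks.items()
        }
        delta = scoring.delta_score(
            combined[self.test.sample_id], combined[self.control.sample_id]
        )
        tdmrs = calling.call_tdmrs(
            delta,
            threshold=threshold,
            min_probes_run=min_probes_run,
            max_gap_bp=max_gap_bp,
            probe_length=self.test.probes.length,
        )
        if self.genes is not None:
            calling.assign_to_genes(tdmrs, self.genes)
        return DifferentialMethylationResults(
            model=self,
            replicate_tracks=tracks,
            combined_tracks=combined,
            delta=delta,
            tdmrs=tdmrs,
            threshold=threshold,
            min_probes_run=min_probes_run,
            max_gap_bp=max_gap_bp,
        )


class DifferentialMethylationResults:
    """Called T-DMRs plus the score tracks they were derived from."""

    def __init__(
        self,
        model: DifferentialMethylation,
        replicate_tracks: Mapping[str, list[ScoreTrack]],
        combined_tracks: Mapping[str, ScoreTrack],
        delta: DeltaTrack,
        tdmrs: list[TDMR],
        threshold: float,
        min_probes_run: int,
        max_gap_bp: int,
    ) -> None:
        self.model = model
        self.replicate_tracks = dict(replicate_tracks)
        self.combined_tracks = dict(combined_tracks)
        self.delta = delta
        self.tdmrs = tdmrs
        self.threshold = threshold
        self.min_probes_run = min_probes_run
        self.max_gap_bp = max_gap_bp

    @property
    def counts(self) -> tuple[int, int, dict[str, int]]:
        return calling.count_by_direction(self.tdmrs)

    def tss_histogram(self, direction: str | None = None):
        sel = [
            t
            for t in self.tdmrs
            if t.gene_id is not None and (direction is None or t.direction == direction)
        ]
        return profiles.tss_distance_histogram(sel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": [t.contig for t in self.tdmrs],
                "start": [t.start for t in self.tdmrs],
                "end": [t.end for t in self.tdmrs],
                "direction": [t.direction for t in self.tdmrs],
                "mean_delta": [t.mean_delta for t in self.tdmrs],
                "n_probes": [t.n_probes for t in self.tdmrs],
                "gene_id": [t.gene_id for t in self.tdmrs],
                "tss_distance": [t.tss_distance for t in self.tdmrs],
                "cluster": [t.cluster for t in self.tdmrs],
            }
        )

    def summary(self) -> str:
        n_test, n_control, gene_counts = self.counts
        lines = [
            "Differential methylation summary",
            "================================",
            f"test sample:        {self.model.test.sample_id}",
            f"control sample:     {self.model.control.sample_id}",
            f"probes scored:      {len(self.delta.records)}",
            f"|Delta| threshold:  {self.threshold}",
            f"min probes per run: {self.min_probes_run}   max gap: {self.max_gap_bp} bp",
            f"T-DMRs called:      {len(self.tdmrs)}",
            f"  hypo in test:     {n_test}"
            f"  (genes: {gene_counts['hypo_in_test']})",
            f"  hypo in control:  {n_control}"
            f"  (genes: {gene_counts['hypo_in_control']})",
        ]
        if self.tdmrs:
            deltas = np.array([t.mean_delta for t in self.tdmrs])
            lines.append(
                f"mean |Delta| of calls: {np.abs(deltas).mean():.3f} "
                f"(range {deltas.min():.3f} .. {deltas.max():.3f})"
            )
        return "\n".join(lines)
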
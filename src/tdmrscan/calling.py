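"""Segment ΔMATscore tracks into T-DMRs and assign them to genes."""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Sequence

import numpy as np

from .types import DeltaTrack, GeneModel, TDMR

logger = logging.getLogger(__name__)


def call_tdmrs(
    delta: DeltaTrack,
    threshold: float = 2.0,
    min_probes_run: int = 4,
    max_gap_bp: int = 300,
    probe_length: int = 25,
) -> list[TDMR]:
    """Maximal same-direction runs of super-threshold probe positions.

    A probe qualifies when Δ ≥ threshold (hypomethylated in test) or
    Δ ≤ −threshold (hypomethylated in control). Consecutive qualifying
    probes extend one run while they share a direction and lie within
    ``max_gap_bp`` of each other; a qualifying probe of the opposite
    direction always closes the run — mixed signs never share a T-DMR.
    Runs with fewer than ``min_probes_run`` qualifying probes are dropped.
    The reported interval spans the first to the last qualifying probe plus
    one probe length.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out: list[TDMR] = []
    for contig, grp in delta.records.groupby("contig", sort=True):
        pos = grp["position"].to_numpy()
        d = grp["delta"].to_numpy()
        qual = np.abs(d) >= threshold
        qpos, qd = pos[qual], d[qual]
        signs = np.sign(qd).astype(int)

        run_start = 0
        for i in range(1, len(qpos) + 1):
            if (
                i < len(qpos)
                and signs[i] == signs[run_start]
                and qpos[i] - qpos[i - 1] <= max_gap_bp
            ):
                continue
            count = i - run_start
            if count >= min_probes_run:
                seg_d = qd[run_start:i]
                direction = "hypo_in_test" if signs[run_start] > 0 else "hypo_in_control"
                out.append(
                    TDMR(
                        contig=str(contig),
                        start=int(qpos[run_start]),
                        end=int(qpos[i - 1]) + probe_length,
                        direction=direction,
                        mean_delta=float(seg_d.mean()),
                        n_probes=int(count),
                    )
                )
            run_start = i
    return out


def assign_to_genes(tdmrs: Sequence[TDMR], genes: Sequence[GeneModel]) -> list[TDMR]:
    """Attach gene and strand-oriented TSS distance by interval midpoint.

    A T-DMR is assigned to the gene whose promoter window contains its
    midpoint (so each call maps to at most one gene). If several windows
    overlap the midpoint, the nearest TSS wins, lexicographically smallest
    gene_id on ties (logged).
    """
    by_contig: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_contig[g.contig].append(g)
    for lst in by_contig.values():
        lst.sort(key=lambda g: g.promoter_window[0])

    for t in tdmrs:
        mid = t.midpoint
        candidates = [g for g in by_contig.get(t.contig, []) if g.contains(mid)]
        if not candidates:
            t.gene_id = None
            t.tss_distance = None
            continue
        if len(candidates) > 1:
            best = min(abs(mid - g.tss) for g in candidates)
            tied = sorted(
                (g for g in candidates if abs(mid - g.tss) == best),
                key=lambda g: g.gene_id,
            )
            if len(tied) > 1:
                logger.info(
                    "T-DMR %s:%d-%d midpoint in %d overlapping windows; "
                    "assigned to %s by TSS distance/lexicographic tie-break",
                    t.contig, t.start, t.end, len(candidates), tied[0].gene_id,
                )
            gene = tied[0]
        else:
            gene = candidates[0]
        t.gene_id = gene.gene_id
        t.tss_distance = gene.offset(mid)
    return list(tdmrs)


def count_by_direction(tdmrs: Sequence[TDMR]) -> tuple[int, int, dict[str, int]]:
    """(n hypo_in_test, n hypo_in_control, unique gene counts per direction)."""
    n_test = sum(1 for t in tdmrs if t.direction == "hypo_in_test")
    n_control = len(tdmrs) - n_test
    genes: dict[str, set] = {"hypo_in_test": set(), "hypo_in_control": set()}
    for t in tdmrs:
        if t.gene_id is not None:
            genes[t.direction].add(t.gene_id)
    return n_test, n_control, {d: len(s) for d, s in genes.items()}
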
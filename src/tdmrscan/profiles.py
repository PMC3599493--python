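"""Characterization of called T-DMRs.

TSS-distance distributions, CpG-island detection and CGI-gene bias,
K-means clustering of ΔMATscore profiles under Pearson correlation
distance, detection of the 5′→3′ hypomethylation position shift, and
hypergeometric term enrichment.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .types import (
    DeltaTrack,
    DistanceHistogram,
    EnrichmentResult,
    GeneModel,
    Interval,
    TDMR,
)

HIST_EDGES = np.arange(-6000, 2501, 250)


def tss_distance_histogram(tdmrs: Sequence[TDMR]) -> DistanceHistogram:
    """Proportions of T-DMR TSS distances per 250-bp bin over [−6 kb, +2.5 kb)."""
    if not tdmrs:
        raise ValueError("cannot build a distance histogram from zero T-DMRs")
    dists = []
    for t in tdmrs:
        if t.tss_distance is None:
            raise ValueError("all T-DMRs must be gene-assigned before binning")
        dists.append(t.tss_distance)
    counts, _ = np.histogram(dists, bins=HIST_EDGES)
    return DistanceHistogram(edges=HIST_EDGES, proportions=counts / counts.sum())


def detect_cgi(
    sequence: str, min_len: int = 200, min_gc: float = 0.5, min_oe: float = 0.6
) -> list[tuple[int, int]]:
    """Gardiner-Garden–Frommer CpG islands as merged passing windows.

    Every ``min_len``-bp window (step 1) with GC fraction ≥ ``min_gc`` and
    CpG obs/exp = (#CG × L)/(#C × #G) ≥ ``min_oe`` is marked; overlapping
    passing windows are merged into maximal intervals, whose bounds are
    exactly the union of passing windows (no outward extension).
    """
    L = len(sequence)
    if L < min_len:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    is_cg[:-1] = is_c[:-1] & is_g[1:]

    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    starts = np.arange(L - min_len + 1)
    nc = cum_c[starts + min_len] - cum_c[starts]
    ng = cum_g[starts + min_len] - cum_g[starts]
    # CG dinucleotides fully inside the window: starts in [s, s+min_len-1)
    ncg = cum_cg[starts + min_len - 1] - cum_cg[starts]
    gc_ok = (nc + ng) / min_len >= min_gc
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(nc * ng > 0, ncg * min_len / np.maximum(nc * ng, 1), 0.0)
    passing = gc_ok & (oe >= min_oe)

    out: list[tuple[int, int]] = []
    idx = np.flatnonzero(passing)
    if idx.size == 0:
        return out
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i > prev + min_len:  # windows no longer overlap -> close island
            out.append((int(run_start), int(prev + min_len)))
            run_start = i
        prev = i
    out.append((int(run_start), int(prev + min_len)))
    return out


def cgi_genes(
    genes: Sequence[GeneModel], cgis: Sequence[Interval], tss_flank: int = 500
) -> set[str]:
    """Genes with a CGI overlapping [tss − flank, tss + flank)."""
    out = set()
    for g in genes:
        lo, hi = g.tss - tss_flank, g.tss + tss_flank
        if hi <= lo:
            lo, hi = g.tss, g.tss + 1  # flank 0: only CGIs containing the TSS base
        for iv in cgis:
            if iv.contig == g.contig and iv.overlaps(lo, hi):
                out.add(g.gene_id)
                break
    return out


def cgi_gene_bias(
    tdmrs: Sequence[TDMR],
    genes: Sequence[GeneModel],
    cgis: Sequence[Interval],
    tss_flank: int = 500,
) -> tuple[dict[str, float], float]:
    """Per-direction proportion of T-DMR genes that are CGI genes, plus Fisher p.

    Returns ({direction: proportion}, two-sided Fisher exact p comparing the
    CGI/non-CGI gene composition of the two directions).
    """
    cgi_set = cgi_genes(genes, cgis, tss_flank)
    table = {}
    for direction in ("hypo_in_test", "hypo_in_control"):
        ids = {t.gene_id for t in tdmrs if t.direction == direction and t.gene_id}
        n_cgi = len(ids & cgi_set)
        table[direction] = (n_cgi, len(ids) - n_cgi)
    props = {
        d: (k / (k + m) if (k + m) else float("nan")) for d, (k, m) in table.items()
    }
    contingency = [list(table["hypo_in_test"]), list(table["hypo_in_control"])]
    _, p = stats.fisher_exact(contingency, alternative="two-sided")
    return props, float(p)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _pearson_normalize(matrix: np.ndarray, flat_norm: float) -> np.ndarray:
    """Center rows and scale by max(row norm, flat_norm).

    With unit-norm rows, squared Euclidean distance is 2(1 − Pearson r), so
    Lloyd's algorithm on the transformed rows is K-means under correlation
    distance. The ``flat_norm`` floor handles the degeneracy of (near-)flat
    rows — Pearson r is undefined at zero profile variance — by shrinking
    them toward the origin instead of inflating noise to the unit sphere.
    """
    centered = matrix - matrix.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    return centered / np.maximum(norms, flat_norm)


def cluster_profiles(
    matrix: np.ndarray | pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    n_init: int = 20,
    flat_norm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation-distance K-means of ΔMATscore profiles.

    Rows are centered and norm-scaled (see ``_pearson_normalize``), then
    clustered with Lloyd's algorithm, best of ``n_init`` restarts by
    within-cluster sum of squares. Returns (labels, cluster mean profiles
    in the original score units).
    """
    values = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if values.ndim != 2:
        raise ValueError("profile matrix must be 2-D")
    if np.isnan(values).any():
        raise ValueError("profile matrix must not contain missing values")
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({values.shape[0]})")
    transformed = _pearson_normalize(values, flat_norm)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(transformed)
    means = np.vstack([values[labels == c].mean(axis=0) for c in range(k)])
    return labels, means


def build_profile_matrix(
    tdmrs: Sequence[TDMR],
    delta_tracks: Mapping[str, DeltaTrack],
) -> pd.DataFrame:
    """Mean ΔMATscore over each T-DMR interval per labeled comparison column."""
    if not tdmrs:
        raise ValueError("no T-DMRs to profile")
    rows = {}
    for i, t in enumerate(tdmrs):
        rid = f"{t.contig}:{t.start}-{t.end}:{i}"
        vals = {}
        for label, track in delta_tracks.items():
            rec = track.records
            sel = (
                (rec["contig"] == t.contig)
                & (rec["position"] >= t.start)
                & (rec["position"] < t.end)
            )
            if not sel.any():
                raise ValueError(f"no probes of track {label!r} inside T-DMR {rid}")
            vals[label] = float(rec.loc[sel, "delta"].mean())
        rows[rid] = vals
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# position shift
# ---------------------------------------------------------------------------


def detect_position_shift(
    gene_id: str,
    tdmr_sets: Mapping[str, Sequence[TDMR]],
    delta_tracks: Mapping[str, DeltaTrack],
    nsph_label: str = "nsph",
    adult_label: str = "adult",
    threshold: float = 2.0,
) -> tuple[bool, dict]:
    """Flag a gene whose hypomethylated region moves from 5′ to 3′ in adulthood.

    Flags iff (a) the gene has a progenitor-stage hypomethylated T-DMR
    upstream of the TSS (tss_distance < 0) that is *not* hypomethylated in
    the adult sample — its mean adult Δ against the same control stays below
    ``threshold`` — and (b) the adult sample has a hypomethylated T-DMR
    downstream (tss_distance > 0). Returns (flag, supporting evidence).
    """
    nsph = [t for t in tdmr_sets.get(nsph_label, []) if t.gene_id == gene_id]
    adult = [t for t in tdmr_sets.get(adult_label, []) if t.gene_id == gene_id]
    if not nsph and not adult and not any(
        t.gene_id == gene_id for ts in tdmr_sets.values() for t in ts
    ):
        raise KeyError(f"gene {gene_id!r} absent from every T-DMR assignment")

    adult_track = delta_tracks[adult_label]
    lost_upstream = []
    for t in nsph:
        if t.direction != "hypo_in_test" or t.tss_distance is None or t.tss_distance >= 0:
            continue
        rec = adult_track.records
        sel = (
            (rec["contig"] == t.contig)
            & (rec["position"] >= t.start)
            & (rec["position"] < t.end)
        )
        adult_delta = float(rec.loc[sel, "delta"].mean()) if sel.any() else 0.0
        if adult_delta < threshold:
            lost_upstream.append((t, adult_delta))

    gained_downstream = [
        t
        for t in adult
        if t.direction == "hypo_in_test"
        and t.tss_distance is not None
        and t.tss_distance > 0
    ]
    flag = bool(lost_upstream) and bool(gained_downstream)
    evidence = {
        "lost_upstream": [(t.start, t.end, d) for t, d in lost_upstream],
        "gained_downstream": [(t.start, t.end) for t in gained_downstream],
    }
    return flag, evidence


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def enrichment(
    query_genes: set[str] | Sequence[str],
    annotation: Mapping[str, set[str] | Sequence[str]],
    universe: set[str] | Sequence[str],
    method: str = "fisher",
) -> list[EnrichmentResult]:
    """One-sided hypergeometric term enrichment with BH correction.

    ``fisher``: upper-tail P(X ≥ k) for overlap k between the query and each
    term. ``ease``: the DAVID-style conservative variant with the overlap
    reduced by one (p = 1 when k ≤ 1). q-values are Benjamini–Hochberg
    across terms.
    """
    if method not in ("fisher", "ease"):
        raise ValueError(f"unknown enrichment method {method!r}")
    universe = set(universe)
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)}")
    N, n = len(universe), len(query)
    results = []
    for term in sorted(annotation):
        members = set(annotation[term]) & universe
        K = len(members)
        k = len(members & query)
        if method == "fisher":
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            p = 1.0 if k <= 1 else float(stats.hypergeom.sf(k - 2, N, K, n))
        results.append((term, k, K, p))
    if not results:
        return []
    pvals = [r[3] for r in results]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentResult(term=t, k=k, K=K, n=n, N=N, p=p, q=float(q))
        for (t, k, K, p), q in zip(results, qvals)
    ]
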
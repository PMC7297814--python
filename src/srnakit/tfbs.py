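"""ChIP-seq TFBS overrepresentation at regulated sRNA loci.

Mean ChIP-seq coverage in a strand-aware window around each locus start is
compared between a query set (e.g. sRNAs downregulated at both timepoints)
and an expression-matched nonregulated background, by Welch's t-test with
Bonferroni correction across transcription-factor tracks.  Expression
matching samples the background proportionally to the query's mean log-CPM
decile occupancy, removing expression level as a confounder of ChIP signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import CoverageTrack

__all__ = [
    "matched_background",
    "locus_signal",
    "locus_signals",
    "test_overrepresentation",
    "profile",
    "classify_bound",
    "EnrichmentResult",
]


def _largest_remainder(raw: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:rem]] += 1
    return base


def matched_background(
    regulated,
    nonregulated,
    expression: pd.Series,
    size: int = 455,
    seed: int = 0,
    n_bins: int = 10,
) -> pd.Index:
    """Expression-matched background sample of nonregulated sRNAs.

    Query mean log-CPM values are split into deciles; the background is
    drawn without replacement from the nonregulated pool stratified by the
    same bin edges, proportionally to the query's decile occupancy
    (largest-remainder rounding hits ``size`` exactly).  Strata too small to
    supply their quota trigger a warning and proportional reallocation to
    the remaining strata.
    """
    regulated = pd.Index(regulated)
    pool = pd.Index(nonregulated).difference(regulated)
    if size > len(pool):
        raise ValueError(f"background size {size} exceeds pool of {len(pool)}")
    rng = np.random.default_rng(seed)

    qvals = expression.reindex(regulated).to_numpy(dtype=float)
    pvals = expression.reindex(pool).to_numpy(dtype=float)
    if np.isnan(qvals).any() or np.isnan(pvals).any():
        raise ValueError("expression values missing for some sRNAs")

    edges = np.quantile(qvals, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    qbin = np.clip(np.digitize(qvals, edges[1:-1]), 0, n_bins - 1)
    pbin = np.clip(np.digitize(pvals, edges[1:-1]), 0, n_bins - 1)

    occupancy = np.bincount(qbin, minlength=n_bins).astype(float)
    want = _largest_remainder(occupancy / occupancy.sum() * size, size)
    avail = np.bincount(pbin, minlength=n_bins)

    # reallocate overflow from starved strata proportionally to spare capacity
    short = want - np.minimum(want, avail)
    if short.sum() > 0:
        warnings.warn(
            f"{int(short.sum())} background draws reallocated from strata with too "
            "few expression-matched nonregulated sRNAs"
        )
        want = np.minimum(want, avail)
        while want.sum() < size:
            spare = avail - want
            weights = np.where(spare > 0, spare, 0).astype(float)
            idx = np.argmax(weights)
            want[idx] += 1

    chosen = []
    for b in range(n_bins):
        members = np.flatnonzero(pbin == b)
        if want[b]:
            take = rng.choice(members, size=int(want[b]), replace=False)
            chosen.append(take)
    chosen = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    return pool[chosen]


def locus_signal(
    track: CoverageTrack,
    row: pd.Series,
    window: int = 1000,
    mode: str = "window",
) -> float:
    """Mean per-base coverage at one locus.

    ``mode="window"``: over [c - window, c + window) around the strand-aware
    5' start c (start on +, end - 1 on -); the divisor stays the full window
    even when clipped at a chromosome edge, consistent with uncovered = 0.
    ``mode="body"``: over the locus interval itself.
    """
    if window < 0:
        raise ValueError("window must be nonnegative")
    if mode == "body":
        return track.interval_mean(row["chrom"], row["start"], row["end"])
    if mode != "window":
        raise ValueError("mode must be 'window' or 'body'")
    center = row["start"] if row["strand"] == "+" else row["end"] - 1
    a = center - window
    b = center + window
    if b <= 0:
        return 0.0
    return track.interval_sum(row["chrom"], max(a, 0), b) / (2 * window if window else 1)


def locus_signals(
    track: CoverageTrack, annotation: pd.DataFrame, window: int = 1000, mode: str = "window"
) -> pd.Series:
    """Per-locus mean coverage for every row of the annotation."""
    vals = [locus_signal(track, row, window, mode) for _, row in annotation.iterrows()]
    return pd.Series(vals, index=annotation.index, name=track.label or "signal")


@dataclass
class EnrichmentResult:
    """Query-vs-background ChIP signal comparison for one TF track."""

    tf: str
    mean_query: float
    mean_background: float
    t: float
    p: float
    p_bonferroni: float
    n_query: int
    n_background: int


def test_overrepresentation(
    query: np.ndarray,
    background: np.ndarray,
    n_tracks: int = 1,
    tf: str = "",
) -> EnrichmentResult:
    """Welch two-sample t-test of query vs background signals, Bonferroni-adjusted."""
    query = np.asarray(query, dtype=float)
    background = np.asarray(background, dtype=float)
    if len(query) < 2 or len(background) < 2:
        raise ValueError("need at least two signal values on each side")
    if n_tracks < 1:
        raise ValueError("n_tracks must be at least 1")
    if np.var(query) == 0 and np.var(background) == 0:
        t, p = (0.0, 1.0) if query.mean() == background.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(query, background, equal_var=False)
        t, p = float(t), float(p)
    return EnrichmentResult(
        tf=tf,
        mean_query=float(query.mean()),
        mean_background=float(background.mean()),
        t=t,
        p=p,
        p_bonferroni=min(1.0, p * n_tracks),
        n_query=len(query),
        n_background=len(background),
    )


def profile(
    track: CoverageTrack,
    loci: pd.DataFrame,
    window: int = 1000,
    bin: int = 50,
):
    """Strand-oriented coverage profiles around locus starts.

    Returns (profile matrix, averaged profile): the matrix has one row per
    locus and one column per ``bin``-bp bin covering [-window, +window)
    relative to the strand-aware 5' start; minus-strand rows are reflected
    so that positive relative positions point into the sRNA body.
    """
    if window % bin != 0:
        raise ValueError("window must be a multiple of bin")
    n_bins = 2 * window // bin
    rows = []
    for _, row in loci.iterrows():
        center = row["start"] if row["strand"] == "+" else row["end"] - 1
        a, b = center - window, center + window
        vals = np.zeros(2 * window)
        lo, hi = max(a, 0), b
        if hi > lo:
            vals[lo - a : hi - a] = track.per_base(row["chrom"], lo, hi)
        if row["strand"] == "-":
            vals = vals[::-1]
        rows.append(vals.reshape(n_bins, bin).mean(axis=1))
    positions = np.arange(-window, window, bin)
    mat = pd.DataFrame(rows, index=loci.index, columns=positions)
    return mat, mat.mean(axis=0)


def classify_bound(
    query_signals: pd.Series,
    background_signals: pd.Series,
    k: float = 2.0,
) -> pd.Series:
    """Bound/unbound partition of query loci against the background signal.

    A locus is called bound when its signal exceeds background mean +
    k * background SD; a degenerate background (SD = 0) falls back to any
    signal strictly above the background mean.
    """
    bg = np.asarray(background_signals, dtype=float)
    sd = bg.std(ddof=1) if len(bg) > 1 else 0.0
    threshold = bg.mean() + (k * sd if sd > 0 else 0.0)
    bound = query_signals > threshold
    bound.name = "bound"
    return bound
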
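"""Sequence-conservation averaging over sRNA loci.

Per-base conservation scores (phastCons-like, in [0, 1]) are consumed as a
bedGraph track; the per-sRNA score is the mean over the locus with
uncovered bases counted as 0.  Summaries are descriptive (count, mean,
median, quartiles) per class and regulation group — no test is attached,
matching how such comparisons are usually reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tracks import CoverageTrack

__all__ = ["mean_conservation", "conservation_scores", "summarize_conservation"]


def mean_conservation(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Mean score over [start, end); uncovered bases contribute 0."""
    if end <= start:
        raise ValueError(f"zero-length interval {chrom}:{start}-{end}")
    return track.interval_sum(chrom, start, end) / (end - start)


def conservation_scores(track: CoverageTrack, annotation: pd.DataFrame) -> pd.Series:
    """Per-sRNA mean conservation over each annotated locus."""
    vals = [
        mean_conservation(track, row["chrom"], row["start"], row["end"])
        for _, row in annotation.iterrows()
    ]
    return pd.Series(vals, index=annotation.index, name="conservation")


# map pattern-classifier direction labels to the reporting groups
_REGULATION_GROUP = {
    "up": "regulated_up",
    "down": "regulated_down",
    "mixed_down_up": "mixed",
    "mixed_up_down": "mixed",
    "none": "nonregulated",
}


def summarize_conservation(
    scores: pd.Series, annotation: pd.DataFrame, calls: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Descriptive statistics per class (and regulation group if calls given).

    Returns a tidy DataFrame with columns class, regulation, n, mean,
    median, q25, q75.  All statistics stay within [0, 1] because the inputs
    do.
    """
    df = pd.DataFrame({"conservation": scores, "class": annotation["class"]})
    if calls is not None:
        df["regulation"] = calls["direction"].map(_REGULATION_GROUP).reindex(df.index)
        df["regulation"] = df["regulation"].fillna("nonregulated")
        keys = ["class", "regulation"]
    else:
        df["regulation"] = "all"
        keys = ["class", "regulation"]
    grouped = df.groupby(keys, sort=True)["conservation"]
    out = grouped.agg(
        n="count",
        mean="mean",
        median="median",
        q25=lambda s: float(np.quantile(s, 0.25)),
        q75=lambda s: float(np.quantile(s, 0.75)),
    ).reset_index()
    return out
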
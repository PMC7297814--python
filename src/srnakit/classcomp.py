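"""Class composition of sRNA sets and the chi-squared comparison.

Regulated sets are compared against randomly sampled nonregulated
backgrounds of matched size; composition differences are tested with a
Pearson chi-squared test on the 2 x k class table (no continuity
correction; the class tables here have k > 2 in practice).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import SRNA_CLASSES

__all__ = ["sample_background", "compose", "chisq_composition"]


def sample_background(nonregulated, size: int, seed: int = 0) -> pd.Index:
    """Uniform seeded sample (without replacement) of nonregulated sRNA ids."""
    pool = pd.Index(nonregulated)
    if size > len(pool):
        raise ValueError(
            f"requested background of {size} but only {len(pool)} nonregulated sRNAs available"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(len(pool), size=size, replace=False)
    return pool[np.sort(take)]


def compose(ids, annotation: pd.DataFrame, classes=None) -> pd.Series:
    """Class counts for a set of sRNA ids (zero-member classes included)."""
    ids = pd.Index(ids)
    missing = ids.difference(annotation.index)
    if len(missing):
        raise KeyError(f"ids missing from annotation: {list(missing[:5])}")
    if classes is None:
        classes = SRNA_CLASSES
    counts = annotation.loc[ids, "class"].value_counts()
    return counts.reindex(classes, fill_value=0).astype(int)


def chisq_composition(a: pd.Series, b: pd.Series):
    """Pearson chi-squared test comparing two class-composition rows.

    Classes empty in both rows are dropped; expected counts come from the
    pooled margins of the resulting 2 x k table; df = k - 1.  Returns
    (statistic, df, p).  Cells with expected counts below 5 raise a warning
    only — small classes are the norm for these data.
    """
    a, b = a.align(b, join="outer", fill_value=0)
    table = pd.DataFrame({"a": a, "b": b})
    table = table.loc[(table["a"] + table["b"]) > 0]
    k = len(table)
    if k < 2:
        raise ValueError("need at least two non-empty classes for the chi-squared test")
    obs = table.to_numpy(dtype=float).T  # 2 x k
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected < 5).any():
        warnings.warn("chi-squared expected counts below 5; p-value is approximate")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p
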
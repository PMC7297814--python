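"""Statistical power for two-group RNA-seq comparisons.

Two procedures: the closed-form normal approximation of Hart et al., driven
by sequencing depth, biological CV, fold-change, per-group n and the
two-sided level alpha; and an empirical shuffle-and-spike simulation that
permutes each sRNA's counts across samples (nulling group structure),
multiplies a random subset by a fold-change in one group, and measures the
fraction recovered by the NB quasi-likelihood test at an FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_adjust, fit_nb_ql
from .quantify import CountMatrix, validate_groups

__all__ = ["hart_power", "hart_sample_size", "shuffle_spike_power", "SpikeSimResult"]


def hart_power(
    fc,
    n: int = 20,
    depth: float = 676.0,
    cv: float = 0.47,
    alpha: float = 0.1,
):
    """Closed-form detection power for a two-group NB RNA-seq comparison.

    power = Phi( sqrt( n * (ln fc)^2 / (2 * (1/depth + cv^2)) ) - z_{1-alpha/2} )

    where depth is the mean count per sRNA, cv the biological coefficient of
    variation and n the per-group sample size.  ``fc`` may be a scalar or an
    array of fold-changes (> 1; callers handle direction).
    """
    fc_arr = np.asarray(fc, dtype=float)
    if n < 2:
        raise ValueError("n must be at least 2")
    if depth <= 0 or cv < 0:
        raise ValueError("depth must be positive and cv nonnegative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if np.any(fc_arr <= 1):
        raise ValueError("fold-change must exceed 1 (direction is handled by the caller)")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    effect = np.sqrt(n * np.log(fc_arr) ** 2 / (2.0 * (1.0 / depth + cv**2)))
    power = stats.norm.cdf(effect - z_alpha)
    return float(power) if np.isscalar(fc) else power


def hart_sample_size(
    fc: float,
    power: float = 0.8,
    depth: float = 676.0,
    cv: float = 0.47,
    alpha: float = 0.1,
) -> float:
    """Per-group n solving the closed form for a target power (convenience)."""
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    if fc <= 1:
        raise ValueError("fold-change must exceed 1")
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return 2.0 * (1.0 / depth + cv**2) * (z / np.log(fc)) ** 2


@dataclass
class SpikeSimResult:
    """Outcome of one shuffle-and-spike run."""

    n_spiked: int
    n_detected: int
    detection_fraction: float
    empirical_fdr: float  # NaN when nothing was detected
    seed: int


def shuffle_spike_power(
    m: CountMatrix,
    groups: pd.Series,
    fc: float,
    spike_fraction: float = 0.1,
    fdr_threshold: float = 0.1,
    seed: int = 0,
    spike_group: str = "RAA",
    shuffle: str = "within",
) -> SpikeSimResult:
    """Empirical power by count shuffling and fold-change spiking.

    Each sRNA's counts are permuted across samples (``shuffle="within"``,
    preserving the per-sRNA count multiset while destroying group
    structure; ``"global"`` permutes the whole matrix instead), a random
    ``spike_fraction`` of sRNAs is multiplied by ``fc`` in ``spike_group``
    (rounded to integers), and the QL F-test plus BH adjustment is run on
    the result.
    """
    if fc <= 0:
        raise ValueError("fc must be positive")
    if not 0 < spike_fraction < 1:
        raise ValueError("spike_fraction must lie in (0, 1)")
    groups = validate_groups(m, groups)
    if spike_group not in set(groups):
        raise ValueError(f"spike group {spike_group!r} not in design")
    rng = np.random.default_rng(seed)

    Y = m.counts.to_numpy(copy=True)
    if shuffle == "within":
        Y = rng.permuted(Y, axis=1)
    elif shuffle == "global":
        flat = Y.ravel()
        rng.shuffle(flat)
        Y = flat.reshape(Y.shape)
    else:
        raise ValueError("shuffle must be 'within' or 'global'")

    G = Y.shape[0]
    n_spiked = int(np.floor(spike_fraction * G))
    spiked = rng.choice(G, size=n_spiked, replace=False)
    cols = np.flatnonzero((groups == spike_group).to_numpy())
    Y[np.ix_(spiked, cols)] = np.maximum(
        np.rint(Y[np.ix_(spiked, cols)] * fc), 0
    ).astype(Y.dtype)

    shuffled = CountMatrix(
        pd.DataFrame(Y, index=m.srna_ids, columns=m.sample_ids),
        lib_sizes=m.lib_sizes.copy(),
    )
    de = fit_nb_ql(shuffled, groups)
    q = bh_adjust(de["p"].to_numpy())
    detected = q < fdr_threshold
    spiked_mask = np.zeros(G, dtype=bool)
    spiked_mask[spiked] = True
    n_det_spiked = int((detected & spiked_mask).sum())
    n_det_total = int(detected.sum())
    fdr = (n_det_total - n_det_spiked) / n_det_total if n_det_total else float("nan")
    return SpikeSimResult(
        n_spiked=n_spiked,
        n_detected=n_det_spiked,
        detection_fraction=n_det_spiked / n_spiked if n_spiked else float("nan"),
        empirical_fdr=fdr,
        seed=seed,
    )
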
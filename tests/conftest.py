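import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from srnakit import CountMatrix, SimConfig, simulate, study_config
from srnakit.tracks import CoverageTrack


@pytest.fixture(scope="session")
def small_study():
    """Small but complete synthetic study shared by read-only tests."""
    cfg = study_config(seed=123, n_srna=400)
    return simulate(cfg)


@pytest.fixture
def tiny_counts():
    """5 sRNAs x 6 samples, two groups, hand-checkable."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(5, 6)),
        index=[f"s{i}" for i in range(5)],
        columns=[f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)],
    )
    return CountMatrix(counts)


def random_track(rng, chrom="chrT", genome=2000, max_intervals=30, score_range=(0.0, 1.0)):
    """Random sorted, non-overlapping scored intervals (shared test helper)."""
    n = int(rng.integers(1, max_intervals))
    cuts = np.sort(rng.choice(np.arange(1, genome), size=min(2 * n, genome - 1), replace=False))
    starts, ends, vals = [], [], []
    for i in range(0, len(cuts) - 1, 2):
        starts.append(int(cuts[i]))
        ends.append(int(cuts[i + 1]))
        vals.append(float(rng.uniform(*score_range)))
    df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": vals})
    return CoverageTrack(df)


def brute_force_interval_mean(track_df, chrom, start, end):
    """Per-base expansion oracle, independent of CoverageTrack internals."""
    dense = np.zeros(end - start)
    sub = track_df[track_df["chrom"] == chrom]
    for _, r in sub.iterrows():
        a, b = max(int(r["start"]), start), min(int(r["end"]), end)
        if b > a:
            dense[a - start : b - start] = r["value"]
    return dense.mean()
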
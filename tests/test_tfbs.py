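import numpy as np
import pandas as pd
import pytest

# alias: the library function's name would otherwise be collected by pytest
from srnakit.tfbs import test_overrepresentation as overrepresentation_test
from srnakit.tfbs import (
    classify_bound,
    locus_signal,
    locus_signals,
    matched_background,
    profile,
)
from srnakit.tracks import CoverageTrack

from conftest import random_track


def track_of(rows):
    return CoverageTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


def locus(start, end, strand="+", chrom="chrT"):
    return pd.Series({"chrom": chrom, "start": start, "end": end, "strand": strand})


class TestMatchedBackground:
    @staticmethod
    def setup_sets(shift=0.0, n_query=100, n_pool=1000, seed=0):
        rng = np.random.default_rng(seed)
        query = pd.Index([f"q{i}" for i in range(n_query)])
        pool = pd.Index([f"p{i}" for i in range(n_pool)])
        expr = pd.Series(
            np.concatenate([rng.normal(5, 2, n_query), rng.normal(5 + shift, 2, n_pool)]),
            index=query.append(pool),
        )
        return query, pool, expr

    def test_identical_distributions_match_decile_histogram(self):
        query, pool, expr = self.setup_sets()
        bg = matched_background(query, pool, expr, size=100, seed=1)
        edges = np.quantile(expr[query], np.linspace(0, 1, 11))
        edges[0], edges[-1] = -np.inf, np.inf
        qh = np.histogram(expr[query], edges)[0]
        bh = np.histogram(expr[bg], edges)[0]
        assert np.abs(qh - bh).max() <= 1

    def test_seed_reproducibility(self):
        query, pool, expr = self.setup_sets()
        a = matched_background(query, pool, expr, size=200, seed=9)
        b = matched_background(query, pool, expr, size=200, seed=9)
        assert list(a) == list(b)

    def test_matching_beats_uniform_sampling_under_shift(self):
        from srnakit.classcomp import sample_background

        query, pool, expr = self.setup_sets(shift=2.0)
        matched_err, uniform_err = [], []
        for s in range(100):
            with pytest.warns(UserWarning):
                bg = matched_background(query, pool, expr, size=150, seed=s)
            matched_err.append(abs(expr[bg].mean() - expr[query].mean()))
            uni = sample_background(pool, 150, seed=s)
            uniform_err.append(abs(expr[uni].mean() - expr[query].mean()))
        assert np.mean(matched_err) < np.mean(uniform_err)

    def test_exact_size_and_disjoint_from_query(self):
        query, pool, expr = self.setup_sets()
        bg = matched_background(query, pool, expr, size=137, seed=2)
        assert len(bg) == 137
        assert len(set(bg) & set(query)) == 0

    def test_oversized_request_rejected(self):
        query, pool, expr = self.setup_sets(n_pool=50)
        with pytest.raises(ValueError):
            matched_background(query, pool, expr, size=100, seed=0)


class TestLocusSignal:
    def test_constant_coverage_returns_constant(self):
        track = track_of([("chrT", 0, 10_000, 3.5)])
        assert locus_signal(track, locus(5000, 5030), window=1000) == pytest.approx(3.5)

    def test_no_coverage_returns_zero(self):
        track = track_of([("chrT", 0, 100, 1.0)])
        assert locus_signal(track, locus(50_000, 50_030), window=1000) == 0.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            track = random_track(rng, score_range=(0, 5))
            start = int(rng.integers(300, 1500))
            strand = "+" if rng.random() < 0.5 else "-"
            row = locus(start, start + 30, strand)
            window = int(rng.integers(1, 250))
            center = start if strand == "+" else start + 30 - 1
            dense = np.zeros(2 * window)
            for _, r in track.data.iterrows():
                a = max(int(r["start"]), center - window)
                b = min(int(r["end"]), center + window)
                if b > a:
                    dense[a - (center - window) : b - (center - window)] = r["value"]
            assert locus_signal(track, row, window=window) == pytest.approx(
                dense.mean(), abs=1e-12
            )

    def test_body_mode_uses_locus_interval(self):
        track = track_of([("chrT", 100, 130, 2.0)])
        assert locus_signal(track, locus(100, 130), mode="body") == pytest.approx(2.0)

    def test_clipped_window_keeps_full_denominator(self):
        # locus near the chromosome start: missing bases count as zero coverage
        track = track_of([("chrT", 0, 10_000, 1.0)])
        val = locus_signal(track, locus(10, 40), window=1000)
        assert val == pytest.approx((1000 + 10) / 2000)


class TestOverrepresentation:
    def test_identical_multisets_null(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        res = overrepresentation_test(vals, vals.copy(), n_tracks=3)
        assert res.p == pytest.approx(1.0)
        assert abs(res.t) < 1e-12

    def test_matches_scipy_welch(self):
        from scipy import stats

        rng = np.random.default_rng(13)
        a, b = rng.normal(1, 1, 40), rng.normal(0, 2, 60)
        res = overrepresentation_test(a, b, n_tracks=4)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)
        assert res.p_bonferroni == pytest.approx(min(1.0, p * 4))

    def test_bonferroni_caps_at_one_and_is_monotone(self):
        rng = np.random.default_rng(14)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r1 = overrepresentation_test(a, b, n_tracks=1)
        r100 = overrepresentation_test(a, b, n_tracks=100)
        assert r1.p_bonferroni <= r100.p_bonferroni <= 1.0

    def test_degenerate_equal_constants(self):
        res = overrepresentation_test(np.full(5, 2.0), np.full(9, 2.0))
        assert res.t == 0.0 and res.p == 1.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_test([1.0], [1.0, 2.0])


class TestProfile:
    def test_peak_at_locus_start_peaks_at_zero(self):
        dense = np.zeros(4000)
        center = 2000
        x = np.arange(4000)
        dense += 5 * np.exp(-0.5 * ((x - center) / 50.0) ** 2)
        track = CoverageTrack.from_dense(np.round(dense, 6), chrom="chrT")
        loci = pd.DataFrame(
            {"chrom": ["chrT"], "start": [center], "end": [center + 30], "strand": ["+"]},
            index=["s0"],
        )
        mat, avg = profile(track, loci, window=1000, bin=50)
        assert abs(int(avg.idxmax())) <= 50

    def test_flat_track_gives_flat_profile(self):
        track = track_of([("chrT", 0, 10_000, 2.0)])
        loci = pd.DataFrame(
            {"chrom": ["chrT"], "start": [5000], "end": [5030], "strand": ["+"]},
            index=["s0"],
        )
        _, avg = profile(track, loci, window=500, bin=50)
        np.testing.assert_allclose(avg, 2.0)

    def test_strand_reflection_reverses_row(self):
        rng = np.random.default_rng(15)
        track = random_track(rng, genome=6000, score_range=(0, 3))
        base = pd.DataFrame(
            {"chrom": ["chrT"], "start": [3000], "end": [3001], "strand": ["+"]},
            index=["s0"],
        )
        flipped = base.copy()
        flipped["strand"] = "-"
        mat_f, _ = profile(track, base, window=500, bin=1)
        mat_r, _ = profile(track, flipped, window=500, bin=1)
        np.testing.assert_allclose(mat_f.iloc[0].to_numpy(), mat_r.iloc[0].to_numpy()[::-1])

    def test_window_must_be_multiple_of_bin(self):
        track = track_of([("chrT", 0, 100, 1.0)])
        with pytest.raises(ValueError):
            profile(track, pd.DataFrame(), window=100, bin=33)


class TestClassifyBound:
    def test_all_below_background_mean_means_none_bound(self):
        query = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        bg = pd.Series(np.linspace(1, 2, 50))
        assert classify_bound(query, bg).sum() == 0

    def test_degenerate_background_falls_back_to_mean(self):
        query = pd.Series([0.9, 1.1], index=list("ab"))
        bg = pd.Series(np.full(10, 1.0))
        bound = classify_bound(query, bg)
        assert not bound["a"] and bound["b"]

    def test_recovers_planted_enrichment(self, small_study):
        truth = small_study.truth
        down = truth.index[truth["pattern"] == "both_down"]
        nonreg = truth.index[truth["pattern"] == "null"]
        track = small_study.chip_tracks["GR"]
        qs = locus_signals(track, small_study.annotation.loc[down], window=1000)
        bs = locus_signals(track, small_study.annotation.loc[nonreg], window=1000)
        bound = classify_bound(qs, bs)
        planted = truth.loc[down, "chip_GR"]
        sensitivity = bound[planted].mean()
        specificity = 1.0 - bound[~planted].mean()
        assert sensitivity >= 0.9 and specificity >= 0.9
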
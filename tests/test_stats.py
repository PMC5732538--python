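import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sipkit.stats import (
    classify_deviation,
    compare_groups,
    dunn_posttest,
    group_summary,
    kruskal_wallis,
    star_levels,
    wilcoxon_effect_size,
)


class TestKruskalWallis:
    def test_identical_observations_guarded(self):
        h, df, p = kruskal_wallis({"a": np.ones(5), "b": np.ones(7), "c": np.ones(3)})
        assert h == 0.0 and df == 2 and p == 1.0

    def test_complete_separation_is_significant(self):
        h, df, p = kruskal_wallis({"a": np.arange(20.0), "b": np.arange(100.0, 120.0)})
        assert p < 0.001 and df == 1

    def test_type_one_error_rate(self, rng):
        # 5 groups from one distribution: rejections at 0.05 should be ~5%
        hits = 0
        reps = 1000
        for _ in range(reps):
            groups = {f"g{i}": rng.normal(0, 1, 20) for i in range(5)}
            _, _, p = kruskal_wallis(groups)
            hits += p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_invariant_under_monotone_transform(self, rng):
        groups = {f"g{i}": rng.uniform(0.1, 2, 15) for i in range(3)}
        h1, _, _ = kruskal_wallis(groups)
        h2, _, _ = kruskal_wallis({k: np.log(v) for k, v in groups.items()})
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_nan_dropped_and_empty_group_excluded(self):
        groups = {"a": np.array([1.0, 2, 3]), "b": np.array([4.0, 5, 6]),
                  "c": np.array([np.nan, np.nan])}
        h, df, p = kruskal_wallis(groups)
        assert df == 1  # group c vanished

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis({"a": np.arange(5.0)})


class TestDunn:
    def test_identical_groups_all_adjusted_one(self):
        g = {k: np.array([1.0, 2, 3, 4, 5]) for k in "abc"}
        table = dunn_posttest(g)
        assert np.allclose(table["p_adj"], 1.0)

    def test_separated_pair_detected_among_five_groups(self, rng):
        g = {f"g{i}": rng.normal(0, 1, 20) for i in range(4)}
        g["far"] = rng.normal(8, 1, 20)
        table = dunn_posttest(g)
        far_rows = table[(table.group_a == "far") | (table.group_b == "far")]
        assert (far_rows["p_adj"] < 0.05).all()
        near = table[~table.index.isin(far_rows.index)]
        assert (near["p_adj"] > 0.05).all()

    def test_z_antisymmetric_under_group_order(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        z_ab = dunn_posttest({"a": a, "b": b})["dunn_z"].iloc[0]
        z_ba = dunn_posttest({"b": b, "a": a})["dunn_z"].iloc[0]
        assert z_ab == pytest.approx(-z_ba)

    def test_two_group_dunn_matches_ranksum_z(self, rng):
        # with k = 2 and no ties, Dunn's statistic reduces to the rank-sum z
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 14)
        z_dunn = dunn_posttest({"a": a, "b": b})["dunn_z"].iloc[0]
        z_w, _, _, _ = wilcoxon_effect_size(a, b)
        assert z_dunn == pytest.approx(z_w, abs=1e-9)


class TestWilcoxonEffectSize:
    def test_identical_samples_zero_effect(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        z, p, r, direction = wilcoxon_effect_size(x, x)
        assert abs(z) < 1e-9 and r < 1e-9 and direction == "none"

    def test_complete_separation_ten_vs_ten(self):
        # rank-sum excess 50, sd sqrt(175): z = 3.78, r = z / sqrt(20) = 0.845
        a = np.arange(100.0, 110)
        b = np.arange(0.0, 10)
        z, p, r, direction = wilcoxon_effect_size(a, b)
        assert z == pytest.approx(50 / np.sqrt(175), abs=1e-9)
        assert r == pytest.approx(0.845, abs=0.001)
        assert direction == "high"

    def test_matches_scipy_mannwhitney_p(self, rng):
        a, b = rng.normal(0, 1, 18), rng.normal(0.5, 1, 25)
        _, p, _, _ = wilcoxon_effect_size(a, b)
        _, p_sp = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=False)
        assert p == pytest.approx(p_sp, rel=1e-6)

    def test_exchange_symmetry(self, rng):
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 11)
        z1, _, r1, d1 = wilcoxon_effect_size(a, b)
        z2, _, r2, d2 = wilcoxon_effect_size(b, a)
        assert r1 == pytest.approx(r2) and z1 == pytest.approx(-z2)
        assert {d1, d2} == {"high", "low"}

    def test_effect_size_bounded_by_one(self, rng):
        for _ in range(200):
            n_a, n_b = rng.integers(2, 15, 2)
            a = rng.normal(rng.uniform(-3, 3), 1, n_a)
            b = rng.normal(0, 1, n_b)
            _, _, r, _ = wilcoxon_effect_size(a, b)
            assert 0.0 <= r <= 1.0

    def test_tiny_samples_use_exact_test(self):
        z, p, r, direction = wilcoxon_effect_size(np.array([2.0]), np.array([1.0, 3.0]))
        assert 0 <= p <= 1 and np.isfinite(z)


class TestClassifyDeviation:
    def _controls(self, rng, loc=0.0):
        return {f"c{i}": rng.normal(loc, 1, 25) for i in range(4)}

    def test_strong_upward_shift_flagged_high(self, rng):
        assert classify_deviation(rng.normal(3, 1, 25), self._controls(rng)) == "high"

    def test_strong_downward_shift_flagged_low(self, rng):
        assert classify_deviation(rng.normal(-3, 1, 25), self._controls(rng)) == "low"

    def test_null_rarely_flagged(self, rng):
        flags = [classify_deviation(rng.normal(0, 1, 25), self._controls(rng))
                 for _ in range(100)]
        assert flags.count("none") >= 95

    def test_partial_dominance_not_flagged(self, rng):
        controls = self._controls(rng)
        controls["c3"] = rng.normal(6, 1, 25)  # one control above the artist
        assert classify_deviation(rng.normal(3, 1, 25), controls) == "none"

    def test_requires_four_controls(self, rng):
        with pytest.raises(ValueError):
            classify_deviation(rng.normal(0, 1, 10), {"c0": rng.normal(0, 1, 10)})


class TestStarsAndSummary:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.00005, "****"),
         (0.05, ""), (0.5, ""), (0.0001, "***"), (0.001, "**"), (0.01, "*")],
    )
    def test_star_mapping(self, p, stars):
        assert star_levels(p) == stars

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            star_levels(1.5)

    def test_percentiles_linear_interpolation(self):
        out = group_summary({"g": np.arange(1.0, 101.0)})
        row = out.iloc[0]
        assert row["median"] == pytest.approx(50.5)
        assert row["p5"] == pytest.approx(5.95)
        assert row["p95"] == pytest.approx(95.05)
        assert row["n"] == 100

    def test_single_value_collapses(self):
        row = group_summary({"g": np.array([3.7])}).iloc[0]
        assert row["median"] == row["p5"] == row["p95"] == 3.7


class TestCompareGroups:
    def _table(self, rng, shift=0.0):
        rows = []
        for g in ("oil", "oil_modern", "graphic", "bad_art", "artist"):
            mu = shift if g == "artist" else 0.0
            for i in range(20):
                rows.append({"image_id": f"{g}_{i}", "group": g,
                             "first_order_entropy": rng.normal(4 + mu, 0.2),
                             "fourier_slope": rng.normal(-2.5, 0.2)})
        return pd.DataFrame(rows)

    def test_planted_shift_produces_flag_and_significance(self, rng):
        table = self._table(rng, shift=1.5)
        report = compare_groups(
            table, artist_groups=["artist"],
            control_groups=["oil", "oil_modern", "graphic", "bad_art"],
        )
        assert report.omnibus.loc["first_order_entropy", "p"] < 1e-4
        assert report.deviation.loc["artist", "first_order_entropy"] == "high"
        assert report.deviation.loc["artist", "fourier_slope"] == "none"

    def test_report_shapes(self, rng):
        report = compare_groups(self._table(rng))
        assert set(report.omnibus.index) == {"first_order_entropy", "fourier_slope"}
        assert len(report.pairwise) == 2 * 10  # 2 measures x C(5,2) pairs
        assert report.deviation is None
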
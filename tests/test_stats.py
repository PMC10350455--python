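import numpy as np
import pytest

from actogram import (
    ActivitySeries,
    ManualScoreSeries,
    compare,
    dunn_posthoc,
    group_summary,
    kruskal_wallis,
    ks_normality,
    spearman,
)

from oracles import dunn_brute, kruskal_brute


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        rs, p = spearman(x, np.exp(x / 10))
        assert rs == pytest.approx(1.0)
        rs, _ = spearman(x, -(x**3))
        assert rs == pytest.approx(-1.0)

    def test_textbook_example(self):
        # Sum d^2 = 4 over n=5 -> rs = 1 - 6*4/(5*24) = 0.8
        rs, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rs == pytest.approx(0.8)

    def test_symmetric_and_transform_invariant(self, rng):
        x, y = rng.random(30), rng.random(30)
        assert spearman(x, y)[0] == pytest.approx(spearman(y, x)[0])
        assert spearman(np.exp(3 * x), y)[0] == pytest.approx(spearman(x, y)[0])

    def test_constant_series_reported_missing(self):
        rs, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rs) and np.isnan(p)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])


class TestKruskalWallis:
    def test_all_identical_is_null(self):
        h, p = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert h == 0.0
        assert p == 1.0

    def test_matches_hand_ranked_toy(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        h, p = kruskal_wallis(groups)
        h_ref, p_ref = kruskal_brute(groups)
        assert h == pytest.approx(h_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_matches_brute_force_with_ties(self, rng):
        groups = [rng.integers(0, 6, 12).astype(float) for _ in range(4)]
        h, p = kruskal_wallis(groups)
        h_ref, p_ref = kruskal_brute(groups)
        assert h == pytest.approx(h_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_transform_invariance(self, rng):
        groups = [rng.random(10) for _ in range(3)]
        h1, _ = kruskal_wallis(groups)
        h2, _ = kruskal_wallis([np.exp(4 * g) for g in groups])
        assert h1 == pytest.approx(h2)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


class TestDunn:
    def test_identical_groups_null(self):
        df = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert df["z"][0] == pytest.approx(0.0, abs=1e-12)
        assert df["p"][0] == pytest.approx(1.0)

    def test_matches_brute_force_on_toy(self):
        # 9 values, 3 groups, with ties to exercise the tie-corrected SE
        groups = [[1.0, 2.0, 2.0], [2.0, 3.0, 4.0], [8.0, 9.0, 9.0]]
        df = dunn_posthoc(groups)
        ref = dunn_brute(groups)
        for _, row in df.iterrows():
            z_ref, p_ref = ref[(int(row["group_i"]), int(row["group_j"]))]
            assert row["z"] == pytest.approx(z_ref, abs=1e-12)
            assert row["p"] == pytest.approx(p_ref, abs=1e-12)

    def test_shifted_group_detected(self, rng):
        base1 = rng.normal(0, 1, 40)
        base2 = rng.normal(0, 1, 40)
        shifted = rng.normal(8, 1, 40)
        df = dunn_posthoc([base1, base2, shifted]).set_index(["group_i", "group_j"])
        assert df.loc[(0, 2), "p"] < 0.001
        assert df.loc[(1, 2), "p"] < 0.001
        assert df.loc[(0, 1), "p"] > 0.05

    def test_adjustment_never_lowers_p(self, rng):
        groups = [rng.random(15) for _ in range(4)]
        raw = dunn_posthoc(groups)["p"].to_numpy()
        for method in ("bonferroni", "holm"):
            adj = dunn_posthoc(groups, adjust=method)["p"].to_numpy()
            assert (adj >= raw - 1e-15).all()


class TestGroupSummary:
    def test_examples(self):
        df = group_summary([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [7.0]])
        assert df.loc[0, "mean"] == 1.0 and df.loc[0, "sem"] == 0.0
        assert df.loc[1, "mean"] == 2.0
        assert df.loc[1, "sem"] == pytest.approx(1.0 / np.sqrt(3), abs=1e-3)
        assert df.loc[2, "sem"] == 0.0 and df.loc[2, "n"] == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_summary([[1.0], []])


class TestKSNormality:
    def test_normal_data_not_rejected(self, rng):
        stat, p = ks_normality(rng.normal(10, 2, 200))
        assert p > 0.05

    def test_uniform_data_rejected(self, rng):
        _, p = ks_normality(rng.random(200))
        assert p < 0.05


class TestCompare:
    def _paired(self, rng, seconds=300):
        # manual score drives activity level, plus noise, at 1 s resolution
        m = rng.integers(0, 4, seconds)
        ts = np.arange(seconds, dtype=float)
        frame_ts = np.arange(seconds * 14) / 14.0
        a = np.repeat(m.astype(float), 14) * 0.02
        a = np.clip(a + rng.normal(0, 0.005, len(a)), 0, 100)
        return ActivitySeries(frame_ts, a), ManualScoreSeries(ts, m)

    def test_report_contains_all_sections(self, rng):
        a, m = self._paired(rng)
        rep = compare(a, m)
        assert {"A~M", "A1~M2", "A0~M1"} <= set(rep.spearman_rs["pair"])
        assert len(rep.ks_normality) == 2
        assert np.isfinite(rep.kruskal_wallis[0])
        assert len(rep.dunn) == 6  # all pairs of 4 M levels
        assert len(rep.group_summaries) == 4
        text = rep.summary()
        for fragment in ("Spearman", "Kruskal-Wallis", "Dunn", "SEM"):
            assert fragment in text

    def test_correlated_series_score_high(self, rng):
        a, m = self._paired(rng)
        rep = compare(a, m)
        rs = rep.spearman_rs.set_index("pair").loc["A~M", "rs"]
        assert rs > 0.8
        # A grouped by M level separates strongly
        assert rep.kruskal_wallis[1] < 1e-6

    def test_json_export(self, tmp_path, rng):
        a, m = self._paired(rng, seconds=240)
        rep = compare(a, m)
        out = tmp_path / "report.json"
        rep.to_json(out)
        import json

        loaded = json.loads(out.read_text())
        assert set(loaded) >= {"spearman", "kruskal_wallis", "dunn",
                               "group_summaries", "ks_normality"}
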
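import numpy as np
import pandas as pd
import pytest

from twostep.inference import (
    jonckheere_terpstra,
    omega_group_pipeline,
    partial_correlation,
    residualize,
    wilcoxon_ranksum,
)


class TestJonckheereTerpstra:
    GROUPS = {"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0]),
              "c": np.array([5.0, 6.0])}

    def test_exact_enumeration_of_saturated_ordering(self):
        res = jonckheere_terpstra(self.GROUPS, ("a", "b", "c"), method="exact")
        assert res.j_stat == 12.0 == res.j_max
        assert res.p_value == pytest.approx(1 / 90)

    def test_montecarlo_matches_exact_within_binomial_error(self):
        exact = jonckheere_terpstra(self.GROUPS, ("a", "b", "c"), method="exact")
        mc = jonckheere_terpstra(self.GROUPS, ("a", "b", "c"), n_perm=20_000,
                                 rng=np.random.default_rng(5))
        tol = 2 * np.sqrt(exact.p_value * (1 - exact.p_value) / 20_000) + 1e-4
        assert abs(mc.p_value - exact.p_value) < tol + 1 / 20_000

    def test_all_ties_give_half_max_and_null_p(self):
        groups = {g: np.full(4, 7.0) for g in ("a", "b", "c")}
        res = jonckheere_terpstra(groups, ("a", "b", "c"), n_perm=500,
                                  rng=np.random.default_rng(1))
        assert res.j_stat == res.j_max / 2
        assert res.p_value > 0.9

    def test_reversed_ordering_mirrors_statistic(self):
        fwd = jonckheere_terpstra(self.GROUPS, ("a", "b", "c"), n_perm=10,
                                  rng=np.random.default_rng(0))
        rev = jonckheere_terpstra(self.GROUPS, ("c", "b", "a"), n_perm=10,
                                  rng=np.random.default_rng(0))
        assert rev.j_stat == fwd.j_max - fwd.j_stat

    def test_seed_reproducible_p(self):
        p1 = jonckheere_terpstra(self.GROUPS, ("a", "b", "c"), n_perm=1000,
                                 rng=np.random.default_rng(3)).p_value
        p2 = jonckheere_terpstra(self.GROUPS, ("a", "b", "c"), n_perm=1000,
                                 rng=np.random.default_rng(3)).p_value
        assert p1 == p2

    def test_unknown_group_in_ordering_raises(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra(self.GROUPS, ("a", "b", "z"))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        _, p = wilcoxon_ranksum(x, x)
        assert p == pytest.approx(1.0)

    def test_exact_small_sample_enumeration(self):
        _, p = wilcoxon_ranksum(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert p == pytest.approx(2 / 6)

    def test_translation_invariance(self):
        a = np.array([1.0, 5.0, 2.0])
        b = np.array([4.0, 7.0, 3.0])
        u1, p1 = wilcoxon_ranksum(a, b)
        u2, p2 = wilcoxon_ranksum(a + 100.0, b + 100.0)
        assert u1 == u2 and p1 == p2


class TestResidualize:
    def test_orthogonal_covariate_returns_centered_values(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        c = np.array([1.0, -1.0, -1.0, 1.0])  # orthogonal to the trend
        res = residualize(y, pd.DataFrame({"c": c}))
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_exact_linear_dependence_leaves_zero(self):
        c = np.linspace(0, 1, 20)
        res = residualize(3.0 + 2.0 * c, pd.DataFrame({"c": c}))
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        C = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = rng.normal(size=50)
        res = residualize(y, C)
        for col in C:
            assert abs(res @ C[col]) < 1e-8 * np.abs(y).sum()

    def test_injected_slope_removed(self):
        rng = np.random.default_rng(8)
        dsst = rng.normal(50, 16, 90)
        omega = 0.4 + 0.005 * (dsst - 50) + rng.normal(0, 0.05, 90)
        res = residualize(omega, pd.DataFrame({"dsst": dsst}))
        slope = np.polyfit(dsst, res, 1)[0]
        assert abs(slope) < 0.01


class TestPartialCorrelation:
    def test_identity_relationship(self, rng):
        x = rng.normal(size=60)
        c = rng.normal(size=60)
        res = partial_correlation(x, x + 1e-9 * rng.normal(size=60),
                                  pd.DataFrame({"c": c}))
        assert res.r > 0.999

    def test_confound_only_association_removed(self, rng):
        c = rng.normal(size=4000)
        x = c + rng.normal(size=4000)
        y = c + rng.normal(size=4000)
        raw = np.corrcoef(x, y)[0, 1]
        res = partial_correlation(x, y, pd.DataFrame({"c": c}))
        assert raw > 0.4 and abs(res.r) < 0.05

    def test_constructed_partial_correlation_recovered(self):
        # build (x, y, c) with known partial correlation 0.5 given c
        rng = np.random.default_rng(2)
        n = 5000
        c = rng.normal(size=n)
        ex = rng.normal(size=n)
        ey = 0.5 * ex + np.sqrt(1 - 0.25) * rng.normal(size=n)
        x = 0.6 * c + ex
        y = -0.4 * c + ey
        res = partial_correlation(x, y, pd.DataFrame({"c": c}))
        assert res.r == pytest.approx(0.5, abs=0.03)

    def test_agrees_with_independent_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame(rng.normal(size=(80, 4)), columns=["x", "y", "c1", "c2"])
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        for method in ("pearson", "spearman"):
            mine = partial_correlation(df["x"], df["y"], df[["c1", "c2"]], method)
            ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                                        method=method)
            assert mine.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
            assert mine.p_value == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_sample_size_guard(self):
        with pytest.raises(ValueError):
            partial_correlation(np.ones(3), np.ones(3), pd.DataFrame({"c": np.ones(3)}))


class TestPipeline:
    @staticmethod
    def _metrics(seed=0, delta=0.1):
        rng = np.random.default_rng(seed)
        rows = []
        for g, mu in (("OCD", 0.35), ("SIB", 0.35 + delta), ("HC", 0.35 + 2 * delta)):
            for i in range(30):
                rows.append({"subject_id": f"{g}{i}", "group": g,
                             "omega_hat": np.clip(rng.normal(mu, 0.12), 0, 1),
                             "age": rng.normal(32, 10),
                             "dsst": rng.normal(50, 16),
                             "ds_backwards": rng.normal(6, 2)})
        return pd.DataFrame(rows)

    def test_full_report_structure(self):
        report = omega_group_pipeline(self._metrics(), n_perm=500, seed=1)
        assert set(report["arm"]) == {"raw", "minus_age", "minus_cognition"}
        jt = report[report["analysis"] == "jonckheere_terpstra"]
        assert len(jt) == 3
        assert (report.groupby("arm").size() == 4).all()  # JT + 3 post-hocs

    def test_ordered_difference_detected(self):
        report = omega_group_pipeline(self._metrics(seed=4, delta=0.12),
                                      n_perm=2000, seed=2)
        p = report[(report["analysis"] == "jonckheere_terpstra")
                   & (report["arm"] == "raw")]["p"].iloc[0]
        assert p < 0.05

    def test_missing_covariate_arm_skipped(self):
        m = self._metrics().drop(columns=["age"])
        report = omega_group_pipeline(m, n_perm=200, seed=0)
        assert "minus_age" not in set(report["arm"])
        assert "raw" in set(report["arm"])
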
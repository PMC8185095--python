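import numpy as np
import pandas as pd
import pytest

from twostep.behavior import (
    build_stay_records,
    compute_subject_metrics,
    correlation_matrix,
    fit_rt_model,
    fit_stay_model,
    repetition_probabilities,
    rt_effect,
    subject_stay_coefs,
)
from twostep.task import TrialRecord

from conftest import simulate_agents
from twostep.agents import HybridParams


def make_trials(choices, rewards, transitions, rt2=None):
    rt2 = rt2 or [800.0] * len(choices)
    recs = []
    for i, (c, r, tr) in enumerate(zip(choices, rewards, transitions)):
        s2 = c if tr == "common" else 1 - c
        recs.append(TrialRecord(i, c, s2, tr, 0, r, 700.0, rt2[i]))
    from twostep.io import trials_to_dataframe

    return trials_to_dataframe(recs)


class TestStayRecords:
    def test_coding_matches_definition(self):
        df = make_trials([0, 0, 1], [1, 0, 1], ["common", "rare", "common"])
        rec = build_stay_records(df)
        assert rec[["stay", "prev_outcome", "prev_transition"]].values.tolist() == \
            [[1, 1, 1], [0, -1, -1]]

    def test_constant_choices_always_stay(self):
        df = make_trials([1] * 10, [0] * 10, ["common"] * 10)
        assert build_stay_records(df)["stay"].eq(1).all()

    def test_record_count_is_trials_minus_one(self):
        df = make_trials([0, 1] * 100, [1, 0] * 100, ["common", "rare"] * 100)
        assert len(build_stay_records(df)) == 199

    def test_fewer_than_two_trials_gives_empty_stream(self):
        df = make_trials([0], [1], ["common"])
        assert build_stay_records(df).empty

    def test_flipping_both_codes_leaves_interaction_invariant(self, rng):
        df = list(simulate_agents(
            HybridParams(0.5, 0.5, 0.5, 4, 4, 0.2, 0.8), 1, "hybrid", 3).values())[0]
        rec = build_stay_records(df)
        c1 = subject_stay_coefs(rec)
        flipped = rec.assign(prev_outcome=-rec["prev_outcome"],
                             prev_transition=-rec["prev_transition"])
        c2 = subject_stay_coefs(flipped)
        assert c1["outcome:transition"] == pytest.approx(c2["outcome:transition"],
                                                         abs=1e-6)


class TestRTEffect:
    def test_hand_example(self):
        df = make_trials([0] * 4, [1] * 4, ["rare", "rare", "common", "common"],
                         rt2=[900.0, 900.0, 800.0, 800.0])
        assert rt_effect(df) == pytest.approx(100.0)

    def test_identical_distributions_give_zero(self):
        df = make_trials([0] * 4, [1] * 4, ["rare", "common", "rare", "common"],
                         rt2=[850.0, 850.0, 850.0, 850.0])
        assert rt_effect(df) == 0.0

    def test_single_trial_per_class(self):
        df = make_trials([0, 0], [1, 1], ["rare", "common"], rt2=[934.0, 828.0])
        assert rt_effect(df) == pytest.approx(106.0)

    def test_missing_class_gives_nan(self):
        df = make_trials([0, 0], [1, 1], ["common", "common"], rt2=[800.0, 820.0])
        assert np.isnan(rt_effect(df))

    def test_shift_invariance_and_scaling(self):
        rt2 = [910.0, 905.0, 790.0, 815.0]
        df = make_trials([0] * 4, [1] * 4, ["rare", "rare", "common", "common"], rt2)
        base = rt_effect(df)
        shifted = df.assign(rt2_ms=df["rt2_ms"] + 123.0)
        scaled = df.assign(rt2_ms=df["rt2_ms"] * 2.0)
        assert rt_effect(shifted) == pytest.approx(base)
        assert rt_effect(scaled) == pytest.approx(2 * base)


class TestRepetitionProbabilities:
    def test_always_stay_agent(self):
        df = make_trials([1] * 20, [1, 1, 0, 0] * 5,
                         ["common", "rare"] * 10)  # populates all four cells
        table = repetition_probabilities(df)
        assert np.allclose(table.to_numpy(float), 1.0)

    def test_mb_agent_shows_crossover(self):
        df = list(simulate_agents(
            HybridParams(0.6, 0.6, 0.0, 8, 8, 0.0, 1.0), 1, "mb", 21, 1000).values())[0]
        t = repetition_probabilities(df)
        assert t.loc["reward", "common"] > t.loc["reward", "rare"]
        assert t.loc["no_reward", "rare"] > t.loc["no_reward", "common"]

    def test_mf_agent_shows_outcome_main_effect(self):
        df = list(simulate_agents(
            HybridParams(0.6, 0.6, 0.9, 8, 8, 0.0, 0.0), 1, "mf", 22, 1000).values())[0]
        t = repetition_probabilities(df)
        assert t.loc["reward"].mean() > t.loc["no_reward"].mean()


class TestStayModel:
    def test_random_stayers_have_null_effects(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(30):
            rows.append(pd.DataFrame({
                "subject_id": f"s{s}",
                "stay": rng.integers(0, 2, 400),
                "prev_outcome": rng.choice([-1, 1], 400),
                "prev_transition": rng.choice([-1, 1], 400),
                "group": None,
            }))
        table = fit_stay_model(pd.concat(rows, ignore_index=True))
        for term in ("outcome", "transition", "outcome:transition"):
            row = table[table["term"] == term].iloc[0]
            assert abs(row["estimate"]) < 0.08  # null-scale effect


class TestRTModel:
    @staticmethod
    def _cohort(effect_by_subject, noise_sd, n_trials, seed):
        rng = np.random.default_rng(seed)
        frames = []
        for sid, (eff, group) in effect_by_subject.items():
            common = rng.random(n_trials) < 0.7
            rt2 = 850.0 + np.where(common, eff, 0.0) + rng.normal(0, noise_sd, n_trials)
            frames.append(pd.DataFrame({
                "subject_id": sid, "group": group,
                "transition": np.where(common, "common", "rare"),
                "rt2_ms": rt2}))
        return pd.concat(frames, ignore_index=True)

    def test_injected_common_shift_recovered(self):
        cohort = self._cohort({f"s{i}": (-75.0, None) for i in range(30)},
                              noise_sd=50.0, n_trials=200, seed=1)
        table = fit_rt_model(cohort)
        est = table.loc[table["term"] == "transition", "estimate"].iloc[0]
        assert est == pytest.approx(-75.0, abs=10.0)

    def test_zero_effect_ci_covers_zero(self):
        cohort = self._cohort({f"s{i}": (0.0, None) for i in range(20)},
                              noise_sd=60.0, n_trials=100, seed=2)
        row = fit_rt_model(cohort).set_index("term").loc["transition"]
        assert abs(row["estimate"]) < 10.0  # null scale vs injected ~60-75 ms

    def test_two_stage_fallback_matches_direction(self):
        cohort = self._cohort({f"s{i}": (-60.0, None) for i in range(10)},
                              noise_sd=40.0, n_trials=100, seed=3)
        row = fit_rt_model(cohort, method="two-stage").set_index("term").loc["transition"]
        assert row["estimate"] == pytest.approx(-60.0, abs=15.0)


class TestCorrelationMatrix:
    def test_hand_rank_example(self):
        m = pd.DataFrame({"x": [1, 2, 3, 4], "y": [2, 1, 4, 3]})
        out = correlation_matrix(m, columns=("x", "y"))
        # d^2 = (1,1,1,1): rho = 1 - 6*4 / (4*(16-1)) = 0.6
        assert out["rho"].iloc[0] == pytest.approx(0.6)

    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([0.3, 1.2, 2.2, 5.0, 9.1])
        m = pd.DataFrame({"x": x, "y": np.exp(x)})
        rho = correlation_matrix(m, columns=("x", "y"))["rho"].iloc[0]
        assert rho == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_flagged_nan(self):
        m = pd.DataFrame({"x": [1, 2, 3, 4], "y": [5, 5, 5, 5]})
        assert np.isnan(correlation_matrix(m, columns=("x", "y"))["rho"].iloc[0])

    def test_too_few_subjects_raises(self):
        m = pd.DataFrame({"x": [1, 2], "y": [2, 1]})
        with pytest.raises(ValueError):
            correlation_matrix(m, columns=("x", "y"))


def test_compute_subject_metrics_assembles_columns(small_cohort):
    _, data = small_cohort
    trials = {s: g for s, g in data.trials.groupby("subject_id")}
    omega = data.truth.set_index("subject_id")["omega"]
    m = compute_subject_metrics(trials, omega, data.covariates)
    assert set(m.columns) >= {"subject_id", "rt_effect_ms", "outcome_coef",
                              "interaction_coef", "omega_hat", "group", "age"}
    assert len(m) == 12 and m["rt_effect_ms"].notna().all()
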
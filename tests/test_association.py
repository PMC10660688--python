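import numpy as np
import pandas as pd
import pytest

from rarliver.association import (ModelSpec, fit_ordinal_logistic,
                                  fit_weighted_linear_log,
                                  fit_weighted_logistic, interaction_test,
                                  sensitivity_exclude_shift, stratified_run,
                                  trend_test)
from rarliver.scoring import assign_quintiles
from rarliver.synthetic import CohortConfig, simulate_biomarkers, simulate_cohort


def make_scored(n=3000, seed=17, log_or=np.log(2.0), modifier_extra=0.0):
    """Scored analytic table with a planted Q1-vs-Q5 effect on GGT.

    The exposure quintile is the generator's latent rhythmicity quintile,
    relabelled as the pseudo-F quintile so the battery can consume it.
    ``modifier_extra`` adds extra Q1 log-odds among diabetics (interaction).
    """
    cfg = CohortConfig(
        n_participants=n, seed=seed,
        true_log_odds={"GGT": {1: log_or}, "ALT": {1: log_or}},
        covariate_log_odds={"GGT": {("diabetes", "yes"): 0.3}}
        if modifier_extra == 0 else {},
        frac_under_20=0.0, frac_80_plus=0.0, pregnancy_rate=0.0,
        frac_no_actigraphy=0.0, frac_few_valid_days=0.0,
        frac_missing_biomarkers=0.0)
    cohort = simulate_cohort(cfg)
    if modifier_extra:
        # redraw GGT with a stronger Q1 effect among diabetics
        rng = np.random.default_rng(seed + 1)
        diab = cohort["diabetes"].to_numpy() == "yes"
        q1 = cohort["exposure_quintile"].to_numpy() == 1
        eta = np.log(0.08 / 0.92) + log_or * q1 + modifier_extra * (q1 & diab)
        redraw = rng.random(n) < 1 / (1 + np.exp(-eta))
    panel = simulate_biomarkers(cohort, cfg, seed)
    if modifier_extra:
        panel["GGT_abnormal_true"] = redraw
        cut = np.where(panel["sex"] == "male", 65.0, 36.0)
        panel["GGT"] = np.where(redraw, cut * 1.5, cut * 0.7)
    df = cohort.merge(panel, on="participant_id")
    labels, _ = assign_quintiles(df["exposure"].to_numpy(),
                                 df["weight"].to_numpy())
    df["pseudo_f_q"] = labels
    from rarliver.scoring import abnormal_flags
    flags = abnormal_flags(df)
    return pd.concat([df, flags], axis=1)


@pytest.fixture(scope="module")
def scored():
    return make_scored()


class TestLogisticBattery:
    def test_planted_or_recovered(self, scored):
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f",
                         adjustment="model1")
        res = fit_weighted_logistic(spec, scored)
        q1 = res.estimates.set_index("contrast").loc["pseudo_f_q[Q1]"]
        assert q1["lower"] < 2.0 < q1["upper"]
        assert res.trend_p < 0.05
        counts = res.diagnostics["per_level"]
        assert counts["n"].sum() == res.n

    def test_full_adjustment_runs(self, scored):
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f",
                         adjustment="model3")
        res = fit_weighted_logistic(spec, scored)
        assert res.converged
        assert len(res.estimates) == 4  # Q1..Q4 vs Q5 reference

    def test_reference_quintile_convention(self, scored):
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f")
        assert spec.reference == 5
        spec_iv = ModelSpec(outcome="GGT", exposure="IV")
        assert spec_iv.reference == 1


class TestLinearAndOrdinal:
    def test_linear_log_levels(self, scored):
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f",
                         outcome_type="loglinear", adjustment="model1")
        res = fit_weighted_linear_log(spec, scored)
        q1 = res.estimates.set_index("contrast").loc["pseudo_f_q[Q1]"]
        assert q1["beta"] > 0  # planted higher GGT odds -> higher levels
        assert q1["lower"] < q1["beta"] < q1["upper"]

    def test_ordinal_composite(self, scored):
        from rarliver.scoring import abnormal_composite
        data = scored.copy()
        data["abnormal_composite"] = abnormal_composite(data)
        spec = ModelSpec(outcome="abnormal_composite", outcome_type="ordinal",
                         exposure="pseudo_f", adjustment="model1")
        res = fit_ordinal_logistic(spec, data)
        q1 = res.estimates.set_index("contrast").loc["pseudo_f_q[Q1]"]
        assert q1["OR"] > 1.0  # impaired rhythmicity raises the composite


class TestTrendAndInteraction:
    def test_trend_detects_dose_response(self, scored):
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f",
                         adjustment="model1")
        assert trend_test(spec, scored) < 0.05

    def test_trend_constant_exposure_errors(self, scored):
        data = scored.copy()
        data["pseudo_f_q"] = 3.0
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f",
                         adjustment="none")
        with pytest.raises(ValueError, match="constant"):
            trend_test(spec, data)

    def test_strong_interaction_detected(self):
        data = make_scored(n=6000, seed=23, modifier_extra=np.log(4.0))
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f",
                         adjustment="none")
        stat, df, p = interaction_test(spec, "diabetes", data)
        assert df == 4
        assert p < 0.05

    def test_constant_modifier_errors(self, scored):
        data = scored.copy()
        data["diabetes"] = "no"
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f", adjustment="none")
        with pytest.raises(ValueError, match="constant"):
            interaction_test(spec, "diabetes", data)


class TestStratifiedAndSensitivity:
    def test_identical_strata_identical_results(self, scored):
        data = pd.concat([scored.assign(stratum="a"),
                          scored.assign(stratum="b")], ignore_index=True)
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f",
                         adjustment="model1")
        out = stratified_run(spec, "stratum", data)
        pd.testing.assert_frame_equal(out["a"].estimates, out["b"].estimates)

    def test_diabetes_only_effect_diverges(self):
        data = make_scored(n=6000, seed=29, log_or=0.0,
                           modifier_extra=np.log(5.0))
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f", adjustment="none")
        out = stratified_run(spec, "diabetes", data)
        or_yes = out["yes"].estimates.set_index("contrast") \
            .loc["pseudo_f_q[Q1]", "OR"]
        or_no = out["no"].estimates.set_index("contrast") \
            .loc["pseudo_f_q[Q1]", "OR"]
        assert or_yes > or_no

    def test_sensitivity_no_flags_identical(self, scored):
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f",
                         adjustment="model1")
        base = fit_weighted_logistic(spec, scored)
        sens = sensitivity_exclude_shift(spec, scored,
                                         np.zeros(len(scored), dtype=bool))
        pd.testing.assert_frame_equal(base.estimates, sens.estimates)
        assert sens.diagnostics["n_removed"] == 0

    def test_sensitivity_all_flagged_errors(self, scored):
        spec = ModelSpec(outcome="GGT", exposure="pseudo_f")
        with pytest.raises(ValueError, match="empty"):
            sensitivity_exclude_shift(spec, scored,
                                      np.ones(len(scored), dtype=bool))
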
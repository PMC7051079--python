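"""Propensity model, nearest-neighbor matching, IPW and balance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msclaims import adjustment, analysis
from msclaims.adjustment import (balance_report, compute_ipw, fit_propensity,
                                 match_nearest, standardized_mean_difference)


def _records(n, treatment, **cols):
    base = {
        "patient_id": np.arange(n),
        "treatment": treatment,
        "age_at_first_claim": 35.0,
        "sex": "F",
        "region": "Southeast",
        "time_to_treatment_months": 3.0,
        "line1_drug": "GLATIRAMER",
        "time_in_line1_years": 1.5,
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestFitPropensity:
    def test_identical_arms_yield_prevalence(self):
        """With covariates identical across arms the model is
        intercept-only: every ps equals the treated prevalence."""
        ages = np.tile([25.0, 35, 45, 55], 5)
        rec = _records(20, treatment=np.r_[np.ones(8), np.zeros(12)].astype(int),
                       age_at_first_claim=np.r_[ages[:8], ages[:12]])
        # make covariate distributions exactly equal between arms
        rec.loc[rec.treatment == 1, "age_at_first_claim"] = [25, 35, 45, 55] * 2
        rec.loc[rec.treatment == 0, "age_at_first_claim"] = [25, 35, 45, 55] * 3
        out, _ = fit_propensity(rec)
        assert np.allclose(out["ps"], 0.4, atol=1e-6)

    def test_saturated_two_cell_fit_matches_cell_frequencies(self):
        """One binary covariate, balanced cells: the logistic MLE is the
        saturated fit, so ps equals the within-cell treated fraction
        (hand-solved 2-parameter likelihood)."""
        rec = _records(8, treatment=[1, 0, 0, 0, 1, 1, 1, 0],
                       sex=["F"] * 4 + ["M"] * 4)
        out, _ = fit_propensity(rec)
        ps = out.set_index("patient_id")["ps"]
        assert np.allclose(ps[:4], 0.25, atol=1e-5)
        assert np.allclose(ps[4:], 0.75, atol=1e-5)

    def test_missing_covariates_listed(self):
        rec = _records(6, treatment=[1, 1, 1, 0, 0, 0])
        rec.loc[2, "region"] = None
        with pytest.raises(ValueError, match=r"missing covariates.*\[2\]"):
            fit_propensity(rec)

    def test_single_arm_is_error(self):
        rec = _records(6, treatment=[1] * 6)
        with pytest.raises(ValueError, match="arm"):
            fit_propensity(rec)

    def test_coefficient_recovery_on_confounded_generator(self):
        """The fitted assignment coefficients recover the generator's
        true logistic coefficients at large n."""
        import msclaims as mc
        cfg = mc.SimulationConfig(n_patients=10000, seed=77)
        truth = mc.generate_population(cfg)
        frame = analysis.truth_analysis_frame(truth)
        _, params = fit_propensity(frame)
        b = cfg.confounder_effects.assignment
        # age enters the truth as (age - 34.7)/10.5; tolerances are wide
        # Monte-Carlo bands (the region indicator carries little
        # information per patient)
        assert params["age_at_first_claim"] * 10.5 == pytest.approx(b["age"], abs=0.10)
        assert params["time_in_line1_years"] == pytest.approx(
            b["time_in_line1"], abs=0.12)
        assert params["region[South]"] == pytest.approx(b["region_south"], abs=0.50)


class TestMatching:
    def _rec(self, treated_ps, control_ps):
        n = len(treated_ps) + len(control_ps)
        rec = _records(n, treatment=[1] * len(treated_ps) + [0] * len(control_ps))
        rec["ps"] = list(treated_ps) + list(control_ps)
        return rec

    def test_nearest_within_caliper(self):
        m = match_nearest(self._rec([0.5], [0.45, 0.7]), seed=0)
        assert len(m.pairs) == 1
        assert m.pairs.iloc[0]["control_id"] == 1  # ps 0.45
        assert m.unmatched_controls == [2]

    def test_caliper_boundary_inclusive(self):
        m = match_nearest(self._rec([0.5], [0.6]), caliper=0.1, seed=0)
        assert len(m.pairs) == 1
        assert m.pairs.iloc[0]["ps_diff"] == pytest.approx(0.1)

    def test_disjoint_supports_match_nothing(self):
        m = match_nearest(self._rec([0.8, 0.9], [0.3, 0.4]), seed=0)
        assert m.pairs.empty
        assert set(m.unmatched_treated) == {0, 1}

    def test_brute_force_two_by_two(self):
        """Greedy order is randomized, but with distances {0.01, 0.02}
        vs crossed {0.11, 0.12} every visit order yields the same pairs
        (brute force over both assignments)."""
        rec = self._rec([0.30, 0.40], [0.31, 0.42])
        for seed in range(6):
            m = match_nearest(rec, seed=seed)
            got = set(zip(m.pairs["treated_id"], m.pairs["control_id"]))
            assert got == {(0, 2), (1, 3)}

    @given(st.lists(st.floats(0.05, 0.95), min_size=2, max_size=14),
           st.lists(st.floats(0.05, 0.95), min_size=2, max_size=14))
    def test_caliper_respected_and_never_increases_pairs(self, tps, cps):
        rec = self._rec(tps, cps)
        with_cal = match_nearest(rec, caliper=0.1, seed=3)
        without = match_nearest(rec, caliper=None, seed=3)
        if len(with_cal.pairs):
            assert (with_cal.pairs["ps_diff"] <= 0.1 + 1e-9).all()
        assert len(without.pairs) >= len(with_cal.pairs)
        # 1:1 without replacement
        assert with_cal.pairs["control_id"].is_unique
        assert with_cal.pairs["treated_id"].is_unique


class TestIPW:
    def test_standard_weights(self):
        rec = _records(4, treatment=[1, 1, 0, 0])
        rec["ps"] = [0.5, 0.25, 0.5, 0.2]
        out = compute_ipw(rec, truncate_percentile=None)
        assert list(out["weight"]) == pytest.approx([2.0, 4.0, 2.0, 1.25])

    def test_paper_literal_mode(self):
        rec = _records(2, treatment=[1, 0])
        rec["ps"] = [0.25, 0.25]
        out = compute_ipw(rec, mode="paper_literal", truncate_percentile=None)
        assert list(out["weight"]) == pytest.approx([4.0, 4.0])

    def test_truncation_caps_extremes(self):
        rec = _records(101, treatment=[1] * 101)
        rec.loc[100, "treatment"] = 0
        rec["ps"] = np.r_[np.full(100, 0.5), 0.999]
        out = compute_ipw(rec, truncate_percentile=99.0)
        assert out["weight"].max() <= np.percentile(
            np.r_[np.full(100, 2.0), 1 / 0.001], 99.0) + 1e-9

    def test_pseudo_population_size(self):
        """Standard ATE weights: each weighted arm totals about the full
        sample size on confounded synthetic data."""
        import msclaims as mc
        cfg = mc.SimulationConfig(n_patients=3000, seed=21)
        frame = analysis.truth_analysis_frame(mc.generate_population(cfg))
        ps_frame, _ = fit_propensity(frame)
        out = compute_ipw(ps_frame, truncate_percentile=None)
        n = len(out)
        for arm in (0, 1):
            total = out.loc[out["treatment"] == arm, "weight"].sum()
            assert total == pytest.approx(n, rel=0.15)


class TestBalance:
    def test_identical_arms_smd_zero(self):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        t = np.array([1, 1, 1, 0, 0, 0])
        assert standardized_mean_difference(x, t) == 0.0

    def test_hand_formula(self):
        x = np.array([2.0, 4, 1, 3])
        t = np.array([1, 1, 0, 0])
        # |3 - 2| / sqrt((1 + 1)/2) with population variances
        assert standardized_mean_difference(x, t) == pytest.approx(1.0)

    def test_report_improves_balance_on_confounded_data(self):
        import msclaims as mc
        cfg = mc.SimulationConfig(n_patients=2000, seed=31)
        frame = analysis.truth_analysis_frame(mc.generate_population(cfg))
        ps_frame, _ = fit_propensity(frame)
        weighted = compute_ipw(ps_frame)
        rep = balance_report(ps_frame, weighted=weighted)
        # confounding is visible pre-adjustment and removed post
        assert rep["smd_pre"].max() > 0.15
        assert rep["smd_post"].max() < rep["smd_pre"].max()
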
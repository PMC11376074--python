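"""Evidence groups, detection summaries, transforms, and the ridge fit."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from oilbiodeg import (
    EvidenceProfile,
    TransformedXY,
    classify_evidence,
    classify_profiles,
    detection_summary,
    fit_ridge,
    select_lambda,
    simulate_expression,
    transform_xy,
)

# The four described co-occurrence patterns; everything else is "other".
DESCRIBED = {
    (True, True, True): 1,
    (True, False, True): 2,
    (False, False, True): 3,
    (False, False, False): 4,
}


class TestEvidenceGroups:
    @pytest.mark.parametrize("flags", list(itertools.product([True, False], repeat=3)))
    def test_truth_table_partitions_all_combinations(self, flags):
        p = EvidenceProfile("s", *flags)
        assert classify_evidence(p) == DESCRIBED.get(flags, "other")

    def test_undefined_flag_refused(self):
        with pytest.raises(ValueError):
            classify_evidence(EvidenceProfile("s", True, None, True))

    def test_vectorized_matches_scalar(self):
        rows = list(itertools.product([True, False], repeat=3))
        df = pd.DataFrame(rows, columns=["has_16s", "has_acra_transcript", "has_alkylcom"])
        groups = classify_profiles(df)
        expected = [DESCRIBED.get(r, "other") for r in rows]
        assert groups.tolist() == expected


class TestDetectionSummary:
    def make(self, degrees, detected, oilfields=None):
        return pd.DataFrame({
            "degree": degrees,
            "oilfield": oilfields or ["SL"] * len(degrees),
            "detected": detected,
        })

    def test_all_detected_is_100_percent(self):
        s = detection_summary(self.make([0, 0, 1], [True, True, True]))
        assert (s["proportion"] == 1.0).all()

    def test_half_detected(self):
        s = detection_summary(self.make([2, 2, 2, 2], [True, True, False, False]))
        row = s[(s.stratum_type == "degree") & (s.stratum == 2)]
        assert row["proportion"].iloc[0] == 0.5 and row["n_total"].iloc[0] == 4

    def test_empty_strata_absent(self):
        s = detection_summary(self.make([0, 4], [True, False]))
        assert set(s[s.stratum_type == "degree"]["stratum"]) == {0, 4}

    def test_weighted_stratum_average_equals_pooled(self):
        rng = np.random.default_rng(0)
        df = self.make(
            rng.integers(0, 5, 200).tolist(),
            rng.random(200) < 0.6,
            rng.choice(["CQ", "SL"], 200).tolist(),
        )
        s = detection_summary(df)
        deg = s[s.stratum_type == "degree"]
        pooled = (deg["proportion"] * deg["n_total"]).sum() / deg["n_total"].sum()
        assert pooled == pytest.approx(df["detected"].mean())

    def test_planted_rates_recovered_within_binomial_bounds(self):
        rates = {0: 0.6, 1: 0.3, 2: 0.5, 3: 1.0, 4: 0.8}
        rng = np.random.default_rng(7)
        degrees = rng.integers(0, 5, 200)
        detected = np.array([rng.random() < rates[d] for d in degrees])
        s = detection_summary(self.make(degrees.tolist(), detected.tolist()))
        for _, row in s[s.stratum_type == "degree"].iterrows():
            p, n = rates[row.stratum], row.n_total
            half_width = 1.96 * np.sqrt(p * (1 - p) / n)
            assert abs(row.proportion - p) <= half_width + 1e-12


class TestTransforms:
    def test_degree_two_maps_to_zero_logit(self):
        t = transform_xy(pd.DataFrame({"g": [1.0]}), np.array([2]))
        assert t.y[0] == pytest.approx(0.0)

    def test_zero_fpkm_with_unit_pseudocount_gives_zero_log(self):
        t = transform_xy(pd.DataFrame({"g": [0.0]}), np.array([1]))
        assert t.x[0, 0] == 0.0

    def test_logit_strictly_increasing_over_degrees(self):
        t = transform_xy(pd.DataFrame({"g": np.ones(5)}), np.arange(5))
        assert np.all(np.diff(t.y) > 0)
        assert np.allclose(t.y, logit((np.arange(5) + 0.5) / 5))

    def test_indeterminate_degrees_excluded_and_counted(self):
        t = transform_xy(pd.DataFrame({"g": [1.0, 2.0, 3.0]}), [0, None, 4])
        assert t.x.shape[0] == 2 and t.n_excluded == 1


class TestRidge:
    def latent_xy(self, seed=0, **kw):
        sim = simulate_expression(seed=seed, **kw)
        return TransformedXY(
            x=sim.log_x, y=sim.latent_response, pseudocount=1.0,
            feature_names=("bacterial_fumarate_addition", "acrA"),
        ), sim

    def test_zero_penalty_equals_least_squares(self):
        t, _ = self.latent_xy(seed=3)
        fit = fit_ridge(t, penalty=0.0)
        design = np.column_stack([t.x, np.ones(len(t.y))])
        ols, *_ = np.linalg.lstsq(design, t.y, rcond=None)
        assert fit.beta == pytest.approx(ols[:2], abs=1e-10)
        assert fit.intercept == pytest.approx(ols[2], abs=1e-10)

    def test_shrinkage_limit(self):
        t, _ = self.latent_xy(seed=3)
        norms = [np.linalg.norm(fit_ridge(t, penalty=lam).beta)
                 for lam in (0.0, 1.0, 100.0, 1e6)]
        assert norms == sorted(norms, reverse=True)
        assert norms[-1] < 1e-3

    def test_coefficient_recovery(self):
        t, sim = self.latent_xy(seed=11)
        fit = fit_ridge(t, penalty=1e-3)
        assert fit.beta == pytest.approx(sim.true_beta, abs=0.05)
        assert fit.intercept == pytest.approx(sim.intercept, abs=0.1)

    def test_intercept_free_mode(self):
        t, _ = self.latent_xy(seed=5)
        fit = fit_ridge(t, penalty=0.0, fit_intercept=False)
        assert fit.intercept == 0.0
        ols, *_ = np.linalg.lstsq(t.x, t.y, rcond=None)
        assert fit.beta == pytest.approx(ols, abs=1e-10)

    def test_negative_penalty_rejected(self):
        t, _ = self.latent_xy()
        with pytest.raises(ValueError):
            fit_ridge(t, penalty=-1.0)

    def test_rank_deficiency_directs_to_penalty(self):
        x = np.ones((10, 2))  # duplicated column
        t = TransformedXY(x=x, y=np.arange(10.0), pseudocount=1.0, feature_names=("a", "b"))
        with pytest.raises(ValueError, match="penalty"):
            fit_ridge(t, penalty=0.0)
        fit_ridge(t, penalty=0.1)  # regularized fit succeeds

    def test_loo_lambda_on_grid(self):
        t, _ = self.latent_xy(seed=9)
        lam = select_lambda(t)
        assert lam in np.logspace(-4, 2, 25)

    def test_archaeal_term_dominates_on_quantized_degrees(self):
        """Even after quantizing the response to integer degrees, the fitted
        acrA coefficient exceeds the bacterial one when beta2 >> beta1."""
        wins = 0
        for seed in range(20):
            sim = simulate_expression(seed=seed)
            t = transform_xy(sim.fpkm, sim.degrees)
            fit = fit_ridge(t, penalty=1e-3)
            wins += fit.beta[1] > fit.beta[0]
        assert wins == 20
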
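"""Rates, d', edge effects, bootstrap, and the model contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from edge_salience import analysis
from edge_salience.io_cli import RunConfig, build_design, simulate
from edge_salience.synthetic_observer import (
    EXP1_DPRIME_MAP,
    EXP2_DPRIME_MAP,
    ObserverParams,
)


class TestRates:
    def test_all_yes_observer(self, small_exp1_responses):
        resp = small_exp1_responses.copy()
        resp["response"] = 1
        rates = analysis.compute_rates(resp, ["participant"])
        assert (rates["hits"] == rates["n_present"]).all()
        assert (rates["false_alarms"] == rates["n_absent"]).all()

    def test_design_counts_in_cells(self, small_exp1_responses):
        rates = analysis.compute_rates(
            small_exp1_responses[small_exp1_responses["order"] == "TM"],
            ["participant", "target_band"])
        assert (rates["n_present"] == 10).all()
        assert (rates["n_absent"] == 10).all()

    def test_random_responder_near_half(self, rng):
        n = 10_000
        resp = pd.DataFrame({
            "participant": 0,
            "present": rng.integers(0, 2, n),
            "response": rng.integers(0, 2, n),
        })
        r = analysis.compute_rates(resp).iloc[0]
        assert r.hits / r.n_present == pytest.approx(0.5, abs=0.03)
        assert r.false_alarms / r.n_absent == pytest.approx(0.5, abs=0.03)

    def test_missing_columns_rejected(self):
        with pytest.raises(KeyError):
            analysis.compute_rates(pd.DataFrame({"response": [1]}))


class TestDprime:
    def test_equal_rates_give_zero(self):
        assert analysis.dprime(5, 10, 5, 10) == pytest.approx(0.0, abs=1e-12)

    def test_inverse_normal_oracle(self):
        # z(0.84) - z(0.16) with negligible correction at 1e6 trials
        n = 10 ** 6
        d = analysis.dprime(int(0.84 * n), n, int(0.16 * n), n)
        want = stats.norm.ppf(0.84) - stats.norm.ppf(0.16)
        assert want == pytest.approx(1.989, abs=1e-3)
        assert d == pytest.approx(want, abs=1e-3)

    def test_loglinear_keeps_perfect_cell_finite(self):
        # closed form with corrected counts: 2*z(10.5/11)
        d = analysis.dprime(10, 10, 0, 10)
        assert np.isfinite(d)
        assert d == pytest.approx(2 * stats.norm.ppf(10.5 / 11), abs=1e-12)
        assert d == pytest.approx(3.381, abs=1e-3)

    def test_uncorrected_perfect_cell_is_infinite(self):
        assert np.isinf(analysis.dprime(10, 10, 0, 10, correction=None))

    def test_clamp_correction(self):
        d = analysis.dprime(10, 10, 0, 10, correction="clamp")
        assert d == pytest.approx(2 * stats.norm.ppf(1 - 0.05), abs=1e-12)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            analysis.dprime(0, 0, 1, 10)

    @given(st.integers(0, 20), st.integers(0, 20))
    @settings(derandomize=True, max_examples=60)
    def test_antisymmetric_in_hits_and_fas(self, h, f):
        d1 = analysis.dprime(h, 20, f, 20)
        d2 = analysis.dprime(f, 20, h, 20)
        assert d1 == pytest.approx(-d2, abs=1e-12)


class TestPrintedMeanArithmetic:
    """The grand-mean contrasts the task's summary statistics report."""

    def test_order_contrast_from_grand_means(self):
        assert -analysis.order_contrast(2.68, 1.58) == pytest.approx(-1.10)

    def test_edge_contrast_from_grand_means(self):
        assert -analysis.edge_contrast(2.54, 1.93) == pytest.approx(-0.61)
        assert analysis.edge_contrast(2.95, 2.55) == pytest.approx(0.40)
        assert analysis.edge_contrast(2.12, 1.31) == pytest.approx(0.81)

    def test_reversed_effect_keeps_sign(self):
        assert analysis.edge_contrast(1.93 - 0.26, 1.93) == pytest.approx(-0.26)


class TestBootstrap:
    def test_constant_data_degenerate_interval(self, rng):
        lo, hi = analysis.bootstrap_ci(np.full(10, 3.3), rng=rng)
        assert (lo, hi) == (3.3, 3.3)

    def test_matches_normal_theory_interval(self, rng):
        x = rng.standard_normal(100)
        lo, hi = analysis.bootstrap_ci(x, b=10_000, rng=rng)
        se = x.std(ddof=1) / 10
        assert lo == pytest.approx(x.mean() - 1.96 * se, abs=0.02)
        assert hi == pytest.approx(x.mean() + 1.96 * se, abs=0.02)

    def test_single_unit_rejected(self, rng):
        with pytest.raises(ValueError):
            analysis.bootstrap_ci([1.0], rng=rng)

    def test_width_shrinks_with_cohort_size(self, rng):
        widths = []
        for n in (10, 40, 160):
            x = rng.standard_normal(n)
            lo, hi = analysis.bootstrap_ci(x, b=4000, rng=rng)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        # ~ 1/sqrt(n): quadrupling n roughly halves the width
        assert widths[0] / widths[2] == pytest.approx(4.0, rel=0.5)


class TestEdgeEffect:
    def test_matches_by_hand_contrast(self, small_exp1_responses):
        res = analysis.edge_effect(small_exp1_responses, b=500,
                                   rng=np.random.default_rng(0))
        t = analysis.dprime_table(small_exp1_responses,
                                  ["participant", "target_band"])
        t["is_edge"] = t["target_band"].isin([1, 6])
        by_hand = (t[t.is_edge].groupby("participant")["dprime"].mean()
                   - t[~t.is_edge].groupby("participant")["dprime"].mean())
        # same construction up to the center-only exclusion of mid trials
        assert res.per_participant.mean() == pytest.approx(by_hand.mean(),
                                                           abs=0.15)
        assert res.ci[0] < res.mean < res.ci[1]

    def test_invariant_to_participant_intercepts(self):
        """Adding a constant to one participant's cells leaves deltas alone."""
        rng = np.random.default_rng(3)
        rows = []
        for p in range(6):
            shift = p * 0.7
            for band in range(1, 7):
                for present in (1, 0):
                    pr = stats.norm.cdf((1.0 + shift) / 2) if present else \
                        stats.norm.sf((1.0 + shift) / 2)
                    for _ in range(30):
                        rows.append({
                            "participant": p, "order": "TM",
                            "target_band": band, "present": present,
                            "response": int(rng.random() < pr),
                        })
        resp = pd.DataFrame(rows)
        res = analysis.edge_effect(resp, b=300, rng=rng)
        # every participant has a flat band profile, so all deltas ~ 0
        assert abs(res.per_participant).max() < 0.8
        assert res.mean == pytest.approx(0.0, abs=0.25)


class TestModels:
    def test_null_data_yields_null_coefficients(self, layout):
        cfg = RunConfig(experiment=1, n_participants=12, master_seed=9,
                        dprime_map={f"{o}/{c}": 1.5 for o in ("TM", "MT")
                                    for c in ("edge", "mid")})
        resp = simulate(cfg, build_design(cfg))
        fit = analysis.fit_mixed_model(resp)
        for name in ("order_tm", "edge", "order_tm:edge", "band"):
            beta = fit.params[name]
            se = abs(beta / fit.tvalues[name]) if fit.tvalues[name] != 0 else 1.0
            assert abs(beta) < 3 * se + 1e-9

    def test_recovers_signs_from_default_cohort(self, small_exp1_responses):
        fit = analysis.fit_mixed_model(small_exp1_responses)
        assert fit.coef("order_tm") > 0 and fit.pvalues["order_tm"] < 0.01
        assert fit.params["edge"] > 0 and fit.pvalues["edge"] < 0.01
        # the edge advantage is larger in the Mixture-Target baseline, so
        # the interaction with the Target-Mixture indicator is negative
        assert fit.params["order_tm:edge"] < 0

    def test_doubling_effect_doubles_coefficient(self, layout):
        betas = []
        for delta in (0.4, 0.8):
            dmap = {("TM", "edge"): 1.5 + delta, ("TM", "mid"): 1.5,
                    ("MT", "edge"): 1.5 + delta, ("MT", "mid"): 1.5}
            cfg = RunConfig(experiment=1, n_participants=40, master_seed=31,
                            participant_sd=0.2)
            cfg.dprime_map = {f"{o}/{c}": v for (o, c), v in dmap.items()}
            resp = simulate(cfg, build_design(cfg))
            fit = analysis.fit_mixed_model(resp, include_msi=False)
            betas.append(fit.params["edge"] + 0.5 * fit.params["order_tm:edge"])
        assert betas[1] == pytest.approx(2 * betas[0], abs=0.25)

    def test_hit_rate_edge_analysis_null_and_recovery(self):
        rng = np.random.default_rng(12)
        fits = {}
        for name, bump in [("null", 0.0), ("bump", 1.2)]:
            dmap = dict(EXP2_DPRIME_MAP)
            for order in ("TM", "MT"):
                for rb in ("low", "high"):
                    base = dmap[(order, rb, "mid")]
                    dmap[(order, rb, "relative-edge")] = base + bump
                    dmap[(order, rb, "center")] = base
            cfg = RunConfig(experiment=2, n_participants=20, master_seed=13)
            cfg.dprime_map = {"/".join(k): v for k, v in dmap.items()}
            resp = simulate(cfg, build_design(cfg))
            fit, rates = analysis.hit_rate_edge_analysis(resp, b=500, rng=rng)
            fits[name] = fit
            assert set(rates["edge_class"]) == {"relative-edge", "center"}
            assert rates["hit_rate"].between(0, 1).all()
        assert fits["null"].pvalues["relative_edge"] > 0.01 or \
            abs(fits["null"].params["relative_edge"]) < 0.3
        assert fits["bump"].params["relative_edge"] > 0
        assert fits["bump"].pvalues["relative_edge"] < 0.01

    def test_adjacent_muting_null_on_homogeneous_observer(
            self, small_exp1_responses):
        fit = analysis.adjacent_muting_contrast(small_exp1_responses)
        assert fit.pvalues["adjacent"] > 0.01

    def test_adjacent_trials_partition(self, small_exp1_responses):
        present = small_exp1_responses[
            (small_exp1_responses["present"] == 1)
            & (small_exp1_responses["muted_band"] >= 0)]
        adj = (present["muted_band"] - present["target_band"]).abs() == 1
        assert len(present) == adj.sum() + (~adj).sum()
        assert adj.sum() > 0 and (~adj).sum() > 0

    def test_adjacency_bonus_recovered(self, layout):
        """An injected adjacency advantage shows up as a positive contrast."""
        cfg = RunConfig(experiment=1, n_participants=15, master_seed=41,
                        participant_sd=0.2)
        resp = simulate(cfg, build_design(cfg))
        present = (resp["present"] == 1) & (resp["muted_band"] >= 0)
        adjacent = (resp["muted_band"] - resp["target_band"]).abs() == 1
        boost = present & adjacent & (resp["response"] == 0)
        rng = np.random.default_rng(42)
        flip = boost & (rng.random(len(resp)) < 0.8)
        resp.loc[flip, "response"] = 1
        fit = analysis.adjacent_muting_contrast(resp)
        assert fit.params["adjacent"] > 0
        assert fit.pvalues["adjacent"] < 0.01


class TestCovariates:
    def test_perfect_and_independent_covariates(self, rng):
        d = rng.normal(2, 0.5, 200)
        assert analysis.covariate_r2(d, d) == pytest.approx(1.0)
        assert analysis.covariate_r2(d, rng.normal(0, 1, 200)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            analysis.covariate_r2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_calibrated_slope_recovers_population_r2(self, layout):
        """msi slope chosen for population R^2 = 0.36 is recovered."""
        # slope s on the raw training score (sd 10) explains
        # s^2*100 / (s^2*100 + participant_sd^2) of d' variance
        cfg = RunConfig(experiment=1, n_participants=200, master_seed=55,
                        msi_training_slope=0.0375, participant_sd=0.5)
        resp = simulate(cfg, build_design(cfg))
        per = analysis.dprime_table(resp, ["participant"]).set_index("participant")
        msi = resp.groupby("participant")["msi_training"].first()
        r2 = analysis.covariate_r2(per["dprime"], msi)
        assert r2 == pytest.approx(0.36, abs=0.12)
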
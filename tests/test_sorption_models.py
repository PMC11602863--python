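import itertools

import numpy as np
import pandas as pd
import pytest

from phsorb.sorption_models import (
    DEFAULT_AL_SITE,
    DEFAULT_FE_SITE,
    MechanisticKdParams,
    Term,
    build_design_matrix,
    contribution_partition,
    empirical_terms,
    fit_kd_model,
    fit_subset_models,
    grid_fit_site_params,
    kendall_screen,
    mechanistic_terms,
    model_ladder,
    predict_kd_mechanistic,
)
from phsorb.speciation import Herbicide, SiteFractionParams
from phsorb.synthetic_data import DEFAULT_TRUTH, simulate_kd

TOY_HERB = Herbicide("toy-acid", pka=3.0)


def toy_soil():
    return {
        "fa_gt2.5L": 2.0,
        "ha": 3.0,
        "hu": 10.0,
        "al_t": 0.5,
        "fe_t": 2.0,
    }


def hand_evaluated_terms(ph=5.0):
    """Step-by-step arithmetic oracle for the mechanistic model at the toy soil."""
    phi_n = 1.0 / (1.0 + 10.0 ** (ph - 3.0))
    phi_an = 1.0 - phi_n
    fp_al = 1.0 / (1.0 + 10.0 ** ((ph - 5.75) / 0.2))
    fp_fe = 1.0 / (1.0 + 10.0 ** ((ph - 2.39) / 1.16))
    return {
        "fa_neutral": phi_n * 2.0 * 0.5,
        "ha_anionic": phi_an * 3.0 * 0.05,
        "hu_anionic": phi_an * 10.0 * 0.02,
        "fa_al_bridge": phi_an * 2.0 * 0.3 * fp_al,
        "al_t_sites": phi_an * 0.5 * 0.4 * fp_al,
        "fe_t_sites": phi_an * 2.0 * 0.1 * fp_fe,
    }


class TestBuildDesignMatrix:
    def test_neutral_column_at_pka_is_half(self, soils18):
        herb = Herbicide("h", pka=float(soils18["ph"].iloc[0]))
        design = build_design_matrix(soils18.head(1), herb, [Term("fa", "n")])
        assert design.frame.iloc[0, 0] == pytest.approx(soils18["fa"].iloc[0] * 0.5)

    def test_anionic_column_far_above_pka(self, soils18):
        herb = Herbicide("h", pka=float(soils18["ph"].min() - 4.0))
        design = build_design_matrix(soils18, herb, [Term("hu", "an")])
        expected = soils18["hu"].to_numpy() * (
            1 - 1 / (1 + 10 ** (soils18["ph"].to_numpy() - herb.pka))
        )
        assert design.frame.iloc[:, 0].to_numpy() == pytest.approx(expected)
        assert np.all(design.frame.iloc[:, 0].to_numpy() >= 0.99 * soils18["hu"].to_numpy())

    def test_site_weighted_column_product_of_factors(self):
        soils = pd.DataFrame(
            {"sample_id": ["s1"], "ph": [5.75], "al_t": [1.0]}
        )
        site = SiteFractionParams(pka_site=5.75, eta=0.2)
        design = build_design_matrix(
            soils, TOY_HERB, [Term("al_t", "an", site=site)]
        )
        phi_an = 1 - 1 / (1 + 10 ** (5.75 - 3.0))
        assert design.frame.iloc[0, 0] == pytest.approx(phi_an * 0.5, rel=1e-6)

    def test_unknown_variable_named_in_error(self, soils18, herbicides):
        with pytest.raises(KeyError, match="no_such_column"):
            build_design_matrix(soils18, herbicides["MCPA"], [Term("no_such_column", "n")])


class TestFitKdModel:
    def test_noise_free_recovery_within_two_percent(self, soils18, kd_noise_free):
        truth = [0.5, 0.05, 0.02, 0.3, 0.4, 0.1]
        herb_name = "MCPB"
        from phsorb.io import DEFAULT_HERBICIDES

        design = build_design_matrix(soils18, DEFAULT_HERBICIDES[herb_name], mechanistic_terms())
        res = fit_kd_model(design, kd_noise_free[herb_name], seed=0)
        for est, t in zip(res.fit.coefficients, truth):
            assert est == pytest.approx(t, rel=0.02)
        assert res.r2 > 0.999

    def test_lambda_zero_equals_constrained_least_squares(self, soils18, kd_noise_free):
        from phsorb.io import DEFAULT_HERBICIDES
        from phsorb.regression import nnls_fit

        herb = DEFAULT_HERBICIDES["2,4-D"]
        design = build_design_matrix(
            soils18.head(10), herb, [Term("fa", "n"), Term("hu", "an"), Term("ha", "an")]
        )
        kd = kd_noise_free["2,4-D"].loc[design.frame.index]
        res = fit_kd_model(design, kd, lambdas=np.array([0.0]), cv=3, seed=0)
        oracle = nnls_fit(design.frame.to_numpy(), kd.to_numpy())
        assert res.fit.coefficients == pytest.approx(oracle, abs=1e-8)

    def test_zero_kd_gives_zero_kappas(self, soils18, herbicides):
        design = build_design_matrix(soils18, herbicides["MCPA"], empirical_terms())
        kd = pd.Series(0.0, index=design.frame.index)
        res = fit_kd_model(design, kd, seed=0)
        assert np.all(res.fit.coefficients == 0.0)

    def test_mismatched_sample_sets_listed(self, soils18, kd_noise_free, herbicides):
        design = build_design_matrix(soils18, herbicides["MCPA"], empirical_terms())
        kd = kd_noise_free["MCPA"].drop(kd_noise_free["MCPA"].index[0])
        with pytest.raises(ValueError, match="do not match"):
            fit_kd_model(design, kd)


class TestPredictMechanistic:
    def test_all_zero_kappas_give_zero(self):
        params = MechanisticKdParams()
        assert predict_kd_mechanistic(toy_soil(), 5.0, TOY_HERB, params) == 0.0

    def test_neutral_limit_at_low_ph(self):
        params = DEFAULT_TRUTH
        kd = predict_kd_mechanistic(toy_soil(), TOY_HERB.pka - 4.0, TOY_HERB, params)
        # Phi_n -> 1: the neutral FA term dominates; anionic terms < 0.01 % of it
        assert kd == pytest.approx(2.0 * 0.5, rel=5e-3)

    def test_toy_soil_matches_hand_evaluation(self):
        expected = hand_evaluated_terms()
        kd = predict_kd_mechanistic(toy_soil(), 5.0, TOY_HERB, DEFAULT_TRUTH)
        assert kd == pytest.approx(sum(expected.values()), rel=1e-12)

    def test_missing_accessibility_variable(self):
        soil = {k: v for k, v in toy_soil().items() if k != "fa_gt2.5L"}
        with pytest.raises(KeyError, match="fa_gt2.5L"):
            predict_kd_mechanistic(soil, 5.0, TOY_HERB, DEFAULT_TRUTH)

    def test_anion_bridge_window_single_interior_maximum(self):
        """Phi_an rises while f_p falls: their product peaks once inside the pH range."""
        ph_grid = np.linspace(2.0, 9.0, 400)
        params = MechanisticKdParams(kappa_al_t_an=1.0, al_site=DEFAULT_AL_SITE)
        vals = np.array(
            [predict_kd_mechanistic(toy_soil(), p, TOY_HERB, params) for p in ph_grid]
        )
        peak = int(np.argmax(vals))
        assert 0 < peak < len(vals) - 1
        diffs = np.sign(np.diff(vals))
        # one sign change: increasing then decreasing
        assert np.sum(np.diff(diffs[diffs != 0]) != 0) == 1


class TestContributionPartition:
    def test_shares_sum_to_one_and_match_oracle(self):
        shares = contribution_partition(DEFAULT_TRUTH, toy_soil(), 5.0, TOY_HERB)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
        expected = hand_evaluated_terms()
        total = sum(expected.values())
        for key, value in expected.items():
            assert shares[key] == pytest.approx(value / total, rel=1e-9)

    def test_single_term_takes_full_share(self):
        params = MechanisticKdParams(kappa_fa_n=1.0)
        shares = contribution_partition(params, toy_soil(), 5.0, TOY_HERB)
        assert shares["fa_neutral"] == pytest.approx(1.0)

    def test_zero_prediction_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            contribution_partition(MechanisticKdParams(), toy_soil(), 5.0, TOY_HERB)


def brute_force_kendall_tau_b(x, y):
    """O(n^2) pair-counting Kendall tau-b with tie correction."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


class TestKendallScreen:
    def test_perfectly_concordant_and_discordant(self):
        kd = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        pred = pd.DataFrame({"up": [1, 2, 3, 4, 5], "down": [5, 4, 3, 2, 1]})
        table = kendall_screen(kd, pred)
        assert table.loc["up", "tau"] == pytest.approx(1.0)
        assert table.loc["down", "tau"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("n", [6, 25, 50])
    def test_matches_brute_force_pair_enumeration(self, n):
        rng = np.random.default_rng(n)
        x = rng.integers(0, 8, n).astype(float)  # integer draws create ties
        y = rng.integers(0, 8, n).astype(float)
        table = kendall_screen(pd.Series(y), pd.DataFrame({"x": x}))
        assert table.loc["x", "tau"] == pytest.approx(brute_force_kendall_tau_b(x, y), abs=1e-12)

    def test_constant_column_reported_as_nan(self):
        kd = pd.Series([1.0, 2.0, 3.0, 4.0])
        table = kendall_screen(kd, pd.DataFrame({"const": [2.0] * 4}))
        assert np.isnan(table.loc["const", "tau"])

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 4"):
            kendall_screen(pd.Series([1.0, 2.0]), pd.DataFrame({"x": [1.0, 2.0]}))


class TestModelLadder:
    def test_generating_stage_attains_maximum_mean_r2_adj(
        self, soils18, kd_noise_free, herbicides
    ):
        results, summary = model_ladder(soils18, kd_noise_free, herbicides, seed=0)
        assert summary["mean_r2_adj"].idxmax() == "mechanistic"

    def test_single_herbicide_mean_equals_its_r2(self, soils18, kd_noise_free, herbicides):
        one = {"MCPA": kd_noise_free["MCPA"]}
        results, summary = model_ladder(
            soils18, one, herbicides, seed=0,
            stages=[("empirical_faL", lambda: empirical_terms())],
        )
        assert len(results) == 1
        assert summary.loc["empirical_faL", "mean_r2_adj"] == pytest.approx(
            results[0].r2_adj
        )


class TestGridFitSiteParams:
    def test_recovers_generator_site_parameters(self, soils18, kd_noise_free, herbicides):
        eta, pka, fits, surface = grid_fit_site_params(
            soils18,
            kd_noise_free,
            herbicides,
            eta_grid=(0.1, 0.2, 0.5),
            pka_grid=(5.25, 5.5, 5.75, 6.0),
            n_lambdas=30,
            cv=5,
        )
        assert (eta, pka) == (0.2, 5.75)
        best = surface.loc[surface["mean_r2_adj"].idxmax()]
        assert all(surface["mean_r2_adj"] <= best["mean_r2_adj"] + 1e-12)

    def test_singleton_grid_returned(self, soils18, kd_noise_free, herbicides):
        one = {"MCPA": kd_noise_free["MCPA"]}
        eta, pka, fits, _ = grid_fit_site_params(
            soils18, one, herbicides, eta_grid=(1.5,), pka_grid=(4.0,), cv=3, n_lambdas=10
        )
        assert (eta, pka) == (1.5, 4.0)

    def test_empty_grid_rejected(self, soils18, kd_noise_free, herbicides):
        with pytest.raises(ValueError, match="non-empty"):
            grid_fit_site_params(soils18, kd_noise_free, herbicides, eta_grid=(), pka_grid=(5.0,))


class TestSubsetModels:
    def test_ph_filter_semantics(self, soils18, kd_noise_free, herbicides):
        results = fit_subset_models(
            soils18, {"MCPB": kd_noise_free["MCPB"]}, herbicides, "low_pH", cv=3
        )
        n_low = int((soils18["ph"] <= 5.6).sum())
        assert len(results[0].residuals) == n_low

    def test_variant_term_sets_structure(self, soils18, kd_noise_free, herbicides):
        low = fit_subset_models(
            soils18, {"MCPB": kd_noise_free["MCPB"]}, herbicides, "low_pH", cv=3
        )[0]
        high = fit_subset_models(
            soils18, {"MCPB": kd_noise_free["MCPB"]}, herbicides, "high_pH", cv=3
        )[0]
        low_names = {t.name for t in low.terms}
        high_names = {t.name for t in high.terms}
        assert any("fp(0.1;4.6)" in n for n in low_names)
        assert any("fp(0.1;7.3)" in n for n in high_names)
        assert not any("ha" in n for n in low_names)
        assert not any(n.startswith("phi_n") for n in high_names)

    def test_low_ph_reduced_model_recovery(self, soils18, herbicides):
        """Data generated from the reduced low-pH structure is recovered."""
        from phsorb.sorption_models import SUBSET_SITE_LOW

        herb = herbicides["MCPB"]
        subset = soils18.loc[soils18["ph"] <= 5.6]
        terms = [
            Term("fa_gt2.5L", "n"),
            Term("fa_gt2.5L", "an"),
            Term("al_t", "an", site=SUBSET_SITE_LOW),
            Term("fe_t", "an", site=SUBSET_SITE_LOW),
        ]
        design = build_design_matrix(subset, herb, terms)
        truth = np.array([0.5, 0.2, 0.4, 0.1])
        y0 = design.frame.to_numpy() @ truth
        rng = np.random.default_rng(5)
        sigma = np.sqrt(np.log1p(0.01**2))
        y = y0 * np.exp(rng.normal(-sigma**2 / 2, sigma, len(y0)))
        kd = pd.Series(y, index=design.frame.index)
        res = fit_kd_model(design, kd, cv=min(5, len(y)), seed=0)
        X = design.frame.to_numpy()
        # The fulvic-acid terms are well identified on the small subset.
        for est, t in zip(res.fit.coefficients[:2], truth[:2]):
            assert est == pytest.approx(t, rel=0.05)
        # The two metal-site columns share the same sharp f_p factor and are
        # nearly collinear on 7 samples; their combined contribution (not the
        # individual split) is the identifiable quantity.
        metal_true = X[:, 2:] @ truth[2:]
        metal_fit = X[:, 2:] @ res.fit.coefficients[2:]
        assert float(metal_fit.sum()) == pytest.approx(float(metal_true.sum()), rel=0.05)
        assert res.fit.predict(X) == pytest.approx(y0, rel=0.05)

    def test_empty_subset_rejected(self, soils18, kd_noise_free, herbicides):
        acid_only = soils18.loc[soils18["ph"] < 4.0]
        with pytest.raises(ValueError, match="no soils"):
            fit_subset_models(
                acid_only, {"MCPA": kd_noise_free["MCPA"]}, herbicides, "high_pH"
            )
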
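"""Fit engine: statistics, residual classification, ranking, recovery."""
import numpy as np
import pytest

from graindry import (
    ContractError,
    brute_force_fit,
    classify_residuals,
    evaluate_model,
    fit_model,
    get_drying_model,
    mean_relative_error_P,
    r_squared,
    rank_models,
    standard_error_SE,
)
from conftest import DRYING_PARAMS_80C


class TestStatistics:
    def test_r_squared_examples(self):
        y = np.array([1.0, 0.5, 0.25])
        assert r_squared(y, y) == pytest.approx(100.0)
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
        assert r_squared(y, [0.9, 0.5, 0.3]) == pytest.approx(
            100 * (1 - 0.0125 / 0.2916666666666667), abs=1e-9
        )
        with pytest.raises(ContractError):
            r_squared([1.0, 1.0], [0.9, 1.1])

    def test_mean_relative_error_examples(self):
        assert mean_relative_error_P([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mean_relative_error_P([1.0, 2.0], [1.1, 1.8]) == pytest.approx(10.0)
        # linear in |residual|
        assert mean_relative_error_P([1.0, 2.0], [1.2, 1.6]) == pytest.approx(20.0)
        with pytest.raises(ContractError):
            mean_relative_error_P([0.0, 1.0], [0.1, 1.0])

    def test_standard_error_examples(self):
        assert standard_error_SE([1.0], [1.0], 1) == 0.0
        assert standard_error_SE([1.0, 1.0], [0.9, 1.1], 2) == pytest.approx(0.1)
        assert standard_error_SE([1.0], [0.7], 1) == pytest.approx(0.3)
        with pytest.raises(ContractError):
            standard_error_SE([1.0], [1.0], 0)

    def test_statistics_match_spreadsheet_formulas(self):
        # independent elementwise re-implementations, random vectors
        rng = np.random.default_rng(7)
        for _ in range(10):
            y = rng.uniform(0.1, 1.0, size=17)
            yhat = y + rng.normal(0, 0.05, size=17)
            p_ref = 100.0 / len(y) * sum(abs(a - b) / a for a, b in zip(y, yhat))
            se_ref = (sum((a - b) ** 2 for a, b in zip(y, yhat)) / 12) ** 0.5
            ss_res = sum((a - b) ** 2 for a, b in zip(y, yhat))
            ss_tot = sum((a - np.mean(y)) ** 2 for a in y)
            r2_ref = 100 * (1 - ss_res / ss_tot)
            assert mean_relative_error_P(y, yhat) == pytest.approx(p_ref, abs=1e-12)
            assert standard_error_SE(y, yhat, 12) == pytest.approx(se_ref, abs=1e-12)
            assert r_squared(y, yhat) == pytest.approx(r2_ref, abs=1e-12)


class TestResidualClassification:
    def test_alternating_signs_are_random(self):
        assert classify_residuals([0.1, -0.1] * 4) == "random"

    def test_monotone_drift_is_tendentious(self):
        assert classify_residuals([0.1] * 4 + [-0.1] * 4) == "tendentious"

    def test_all_zero_residuals_random_by_convention(self):
        assert classify_residuals([0.0] * 8) == "random"

    def test_single_sign_is_tendentious(self):
        assert classify_residuals([0.1] * 8) == "tendentious"

    def test_zeros_inherit_previous_sign(self):
        # equivalent to [+,+,-,-,+,+,-,-]: 4 runs of 8, not significant
        assert classify_residuals([0.1, 0.0, -0.1, 0.0, 0.1, 0.0, -0.1, 0.0]) == (
            classify_residuals([0.1, 0.1, -0.1, -0.1, 0.1, 0.1, -0.1, -0.1])
        )

    def test_needs_five_residuals(self):
        with pytest.raises(ContractError):
            classify_residuals([0.1, -0.1])


class TestFitModel:
    def test_newton_recovery_from_printed_rate(self, time_grid):
        y = evaluate_model("newton", {"k": 0.4636}, time_grid)
        res = fit_model(time_grid, y, get_drying_model("newton"))
        assert res.params["k"] == pytest.approx(0.4636, abs=1e-5)
        assert res.r2_pct == pytest.approx(100.0, abs=1e-6)
        assert res.converged

    def test_constant_response_pushes_rate_to_lower_bound(self, time_grid):
        # MR never decays, so the rate collapses onto the lower boundary
        # region of its box (zero is outside the bounds)
        res = fit_model(time_grid, np.ones_like(time_grid),
                        get_drying_model("newton"))
        assert res.params["k"] < 1e-3
        assert res.converged

    def test_wrong_model_has_larger_sse_than_generating_model(self):
        t = np.linspace(0, 2.5, 10)
        y = evaluate_model("page", {"k": 0.29353, "n": 1.61707}, t)
        newton = fit_model(t, y, get_drying_model("newton"))
        page = fit_model(t, y, get_drying_model("page"))
        assert page.sse < 1e-10
        assert newton.sse > 1e-4
        # grid oracle confirms the newton optimum is genuinely the best newton
        oracle = brute_force_fit(
            t, y, get_drying_model("newton"), step=1e-4, bounds={"k": (0.01, 10.0)}
        )
        assert newton.sse <= np.sum(
            (evaluate_model("newton", oracle, t) - y) ** 2
        ) + 1e-10

    def test_contracts(self, time_grid):
        spec = get_drying_model("newton")
        with pytest.raises(ContractError):
            fit_model([1.0], [1.0], spec)  # too few points
        with pytest.raises(ContractError):
            fit_model([1.0, 1.0, 1.0], [1.0, 0.5, 0.2], spec)  # degenerate x
        with pytest.raises(ContractError):
            fit_model(time_grid, np.full_like(time_grid, np.nan), spec)

    def test_deterministic_given_seed(self, time_grid):
        y = evaluate_model("page", {"k": 0.3, "n": 1.5}, time_grid)
        a = fit_model(time_grid, y, get_drying_model("page"), seed=3)
        b = fit_model(time_grid, y, get_drying_model("page"), seed=3)
        assert a.params == b.params and a.sse == b.sse

    @pytest.mark.parametrize("name", sorted(DRYING_PARAMS_80C))
    def test_noiseless_curve_recovery_all_models(self, name):
        """Every registered model refits its own noiseless output to ~zero SSE."""
        t = np.linspace(0, 2.6, 12)
        y = evaluate_model(name, DRYING_PARAMS_80C[name], t)
        res = fit_model(t, y, get_drying_model(name),
                        init=DRYING_PARAMS_80C[name])
        assert res.sse < 1e-9, name

    @pytest.mark.parametrize(
        "name,ranges",
        [
            ("newton", {"k": (0.1, 3.0)}),
            ("page", {"k": (0.1, 2.0), "n": (0.6, 2.5)}),
            ("page_modified", {"k": (0.1, 2.0), "n": (0.6, 2.5)}),
            ("henderson_pabis", {"a": (0.8, 1.2), "k": (0.1, 3.0)}),
            ("wang_singh", {"a": (-0.35, -0.1), "b": (0.001, 0.02)}),
            ("logarithmic", {"a": (0.8, 1.2), "k": (0.3, 2.0), "c": (-0.15, 0.15)}),
            ("two_exponential_terms", {"a": (1.2, 2.4), "k": (0.3, 2.0)}),
        ],
    )
    def test_random_parameter_recovery_identifiable_models(self, name, ranges):
        """Random draws from identifiable models are recovered to 1e-3 relative."""
        rng = np.random.default_rng(11)
        spec = get_drying_model(name)
        n_ok = 0
        draws = 12
        for _ in range(draws):
            truth = {p: rng.uniform(*ranges[p]) for p in spec.param_names}
            t = np.linspace(0, 2.6, 12)
            y = evaluate_model(name, truth, t)
            res = fit_model(t, y, spec, n_starts=8, seed=5)
            ok = all(
                abs(res.params[p] - truth[p]) <= 1e-3 * max(abs(truth[p]), 1e-3)
                for p in truth
            )
            n_ok += ok
        assert n_ok >= round(0.95 * draws), f"{name}: {n_ok}/{draws}"

    def test_gaussian_noise_leaves_rate_unbiased(self):
        # 60 replicates, sigma=0.01, n=21: mean recovered k within 2 MCSE of truth
        rng = np.random.default_rng(123)
        t = np.linspace(0, 4, 21)
        clean = evaluate_model("newton", {"k": 0.5}, t)
        ks = []
        for _ in range(60):
            y = clean + rng.normal(0, 0.01, size=t.size)
            ks.append(
                fit_model(t, y, get_drying_model("newton"), n_starts=2).params["k"]
            )
        ks = np.array(ks)
        mcse = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - 0.5) < 2 * mcse + 1e-4


class TestRanking:
    def _result(self, **kw):
        from graindry import FitResult

        base = dict(
            model_name="m", params={}, r2_pct=99.0, se=0.01, p_pct=2.0,
            residual_class="random", n_obs=10, glr=8, converged=True, sse=0.001,
        )
        base.update(kw)
        return FitResult(**base)

    def test_single_result_ranks_first(self):
        ranked = rank_models([self._result()])
        assert ranked[0][1] == "acceptable"

    def test_lower_se_wins_ties(self):
        a = self._result(model_name="a", se=0.02)
        b = self._result(model_name="b", se=0.01)
        ranked = rank_models([a, b])
        assert [r.model_name for r, _ in ranked] == ["b", "a"]

    def test_random_residuals_dominate_se(self):
        good = self._result(model_name="good", se=0.05)
        drifty = self._result(
            model_name="drifty", se=0.001, residual_class="tendentious"
        )
        ranked = rank_models([good, drifty])
        assert ranked[0][0].model_name == "good"
        assert ranked[1][1] == "rejected"

    def test_high_p_is_marginal(self):
        ranked = rank_models([self._result(p_pct=25.0)])
        assert ranked[0][1] == "marginal"

    def test_mixed_data_lengths_rejected(self):
        with pytest.raises(ContractError):
            rank_models([self._result(n_obs=10), self._result(n_obs=12)])


class TestBruteForce:
    def test_recovers_newton_rate(self):
        t = np.linspace(0, 3, 15)
        y = evaluate_model("newton", {"k": 0.5}, t)
        oracle = brute_force_fit(
            t, y, get_drying_model("newton"), step=1e-3, bounds={"k": (0.01, 10)}
        )
        assert oracle["k"] == pytest.approx(0.5, abs=1e-3)

    def test_rejects_more_than_two_parameters(self):
        with pytest.raises(ContractError):
            brute_force_fit([0, 1, 2], [1, 0.5, 0.2],
                            get_drying_model("midilli"))

    def test_rejects_degenerate_bounds(self):
        with pytest.raises(ContractError):
            brute_force_fit(
                [0, 1, 2], [1.0, 0.5, 0.2], get_drying_model("newton"),
                bounds={"k": (1.0, 1.0)},
            )
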
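"""Hierarchical model fits, LOO/ELPD machinery and comparison tables."""

import warnings

import numpy as np
import pandas as pd
import pytest

from percmem import (
    ConvergenceWarning,
    build_basis,
    compare_models,
    fit_additive,
    fit_dual,
    fit_hierarchical_linear,
    loo_elpd,
    synthesize_curve,
    weight_contrast_fraction,
)
from percmem.models import FitResult, LooResult, _make_cells

pytestmark = pytest.mark.filterwarnings("ignore::percmem.sampler.ConvergenceWarning")


def _linear_data(rng, alpha=0.5, beta=-0.1, n_parts=8, reps=50, noise=0.2):
    rows = []
    for i in range(n_parts):
        a = alpha + 0.05 * rng.standard_normal()
        b = beta + 0.02 * rng.standard_normal()
        for _ in range(reps):
            for seg in range(1, 11):
                rows.append(
                    (f"s{i}", seg, a + b * (seg - 1) + noise * rng.standard_normal())
                )
    return pd.DataFrame(rows, columns=["participant", "segment_index", "bias"])


def _curve_data(rng, curve, scales, reps=100, noise=0.3):
    rows = []
    for p, s in scales.items():
        for _ in range(reps):
            for seg in range(1, len(curve) + 1):
                rows.append((p, seg, s * curve[seg - 1] + noise * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["participant", "segment_index", "bias"])


class TestHierarchicalLinear:
    def test_parameter_recovery(self, rng, quick_mcmc):
        df = _linear_data(rng)
        fit = fit_hierarchical_linear(df, quick_mcmc)
        summary = fit.summary()
        assert summary.loc["alpha", "ci_lo"] < 0.5 < summary.loc["alpha", "ci_hi"]
        assert summary.loc["beta", "ci_lo"] < -0.1 < summary.loc["beta", "ci_hi"]
        assert summary.loc["sigma", "mean"] == pytest.approx(0.2, abs=0.03)
        # HPDI is never wider than the equal-tailed interval on the same draws
        hpdi_w = summary["hpdi_hi"] - summary["hpdi_lo"]
        ci_w = summary["ci_hi"] - summary["ci_lo"]
        assert np.all(hpdi_w <= ci_w + 1e-12)

    def test_null_data_centers_at_zero(self, quick_mcmc):
        rows = [
            (p, seg, 0.0)
            for p in ("a", "b", "c", "d")
            for seg in range(1, 11)
            for _ in range(20)
        ]
        df = pd.DataFrame(rows, columns=["participant", "segment_index", "bias"])
        fit = fit_hierarchical_linear(df, quick_mcmc)
        assert abs(fit.draws["alpha"].mean()) < 0.05
        assert abs(fit.draws["beta"].mean()) < 0.05

    def test_degenerate_inputs_rejected(self, quick_mcmc):
        with pytest.raises(ValueError):
            fit_hierarchical_linear(
                pd.DataFrame(columns=["participant", "segment_index", "bias"]),
                quick_mcmc,
            )
        single = pd.DataFrame(
            {"participant": ["a"] * 20, "segment_index": list(range(1, 11)) * 2,
             "bias": np.zeros(20)}
        )
        with pytest.raises(ValueError):
            fit_hierarchical_linear(single, quick_mcmc)
        bad = pd.DataFrame(
            {"participant": ["a", "b"], "segment_index": [1, 2],
             "bias": [0.0, np.nan]}
        )
        with pytest.raises(ValueError):
            fit_hierarchical_linear(bad, quick_mcmc)


class TestAdditive:
    def test_curve_and_scaling_recovery(self, rng, quick_mcmc):
        basis = build_basis(10)
        w_true = np.array([-0.1, -0.6, -0.4, -0.05, 0.0, 0.0])
        curve = synthesize_curve(basis, w_true)
        scales = {"p1": 0.5, "p2": 1.0, "p3": 2.0}
        fit = fit_additive(_curve_data(rng, curve, scales), basis, quick_mcmc)
        mean_curve = np.einsum(
            "cdk,sk->s", fit.draws["w_spline"], basis.matrix
        ) / np.prod(fit.draws["w_spline"].shape[:2])
        corr = np.corrcoef(mean_curve, curve)[0, 1]
        assert corr >= 0.95
        w_p = fit.draws["w_P"].mean(axis=(0, 1))
        assert w_p[0] < w_p[1] < w_p[2]  # recovered ordering matches generation
        assert np.all(fit.draws["w_P"] > 0)  # log-normal support

    def test_null_data_gives_flat_curve(self, quick_mcmc):
        basis = build_basis(10)
        rows = [
            (p, seg, 0.0)
            for p in ("a", "b")
            for seg in range(1, 11)
            for _ in range(20)
        ]
        df = pd.DataFrame(rows, columns=["participant", "segment_index", "bias"])
        fit = fit_additive(df, basis, quick_mcmc)
        curves = fit.predicted_curves()["all"]
        assert np.all(np.abs(curves) < 0.05)

    def test_basis_mismatch_rejected(self, rng, quick_mcmc):
        df = _linear_data(rng, n_parts=2, reps=5)
        with pytest.raises(ValueError):
            fit_additive(df, build_basis(8), quick_mcmc)


@pytest.fixture(scope="module")
def shared_curve_fit(quick_mcmc):
    """Correlated-variant fit on data sharing one curve across conditions."""
    rng = np.random.default_rng(21)
    basis = build_basis(10)
    curve = synthesize_curve(basis, np.array([-0.15, -0.55, -0.35, -0.05, 0, 0]))
    rows = []
    for p in ("p1", "p2", "p3", "p4"):
        for cond in ("perception", "memory"):
            for _ in range(40):
                for seg in range(1, 11):
                    rows.append(
                        (p, seg, cond, curve[seg - 1] + 0.3 * rng.standard_normal())
                    )
    df = pd.DataFrame(
        rows, columns=["participant", "segment_index", "condition", "bias"]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_dual(df, basis, "correlated", quick_mcmc)


class TestDual:
    def test_rho_concentrates_above_zero_on_shared_curves(self, shared_curve_fit):
        rho = shared_curve_fit.draws["rho"]
        assert (rho > 0).mean() > 0.9
        assert rho.mean() > 0.2

    def test_identical_variant_ties_weights(self, shared_curve_fit, quick_mcmc):
        # identical variant exposes one weight vector under both names
        rng = np.random.default_rng(3)
        basis = build_basis(10)
        df = pd.DataFrame(
            {
                "participant": np.repeat(["a", "b"], 40),
                "segment_index": np.tile(np.arange(1, 11), 8),
                "condition": np.tile(np.repeat(["perception", "memory"], 20), 2),
                "bias": rng.normal(0, 0.3, 80),
            }
        )
        fit = fit_dual(df, basis, "identical", quick_mcmc)
        np.testing.assert_array_equal(
            fit.draws["w_spline_perception"], fit.draws["w_spline_memory"]
        )
        frac = weight_contrast_fraction(fit)
        assert set(frac) == {"a", "b"}

    def test_unknown_variant_and_missing_condition_rejected(self, quick_mcmc):
        basis = build_basis(10)
        df = pd.DataFrame(
            {
                "participant": ["a", "b"],
                "segment_index": [1, 2],
                "condition": ["perception", "perception"],
                "bias": [0.0, 0.1],
            }
        )
        with pytest.raises(ValueError):
            fit_dual(df, basis, "entangled", quick_mcmc)
        with pytest.raises(ValueError):
            fit_dual(df, basis, "identical", quick_mcmc)


class TestLoo:
    def _normal_mean_fit(self, rng, n=200):
        """Known-sigma normal-mean model with its analytic posterior."""
        y = rng.standard_normal(n)
        df = pd.DataFrame(
            {"participant": "a", "segment_index": 1, "bias": y}
        )
        cells = _make_cells(df, ("a",), 1)
        post = y.mean() + rng.standard_normal((4, 500)) / np.sqrt(n)
        return FitResult(
            model="normal_mean",
            draws={"mu": post},
            participants=("a",),
            conditions=("all",),
            _cells={"all": cells},
            _mu_cells={"all": post[:, :, None, None]},
            _sigma={"all": np.ones_like(post)},
        )

    def test_elpd_matches_analytic_normal_predictive(self, rng):
        fit = self._normal_mean_fit(rng)
        loo = loo_elpd(fit)
        n = fit.n_obs
        analytic = n * (-0.5 * np.log(2 * np.pi) - 0.5)
        assert abs(loo.elpd - analytic) < 3 * loo.se
        assert loo.loo_i.size == n
        assert np.all(loo.pareto_k < 0.7)

    def test_identical_fits_have_zero_delta(self, rng):
        fit = self._normal_mean_fit(rng)
        loo = loo_elpd(fit)
        table = compare_models({"a": loo, "b": loo})
        assert table["delta_elpd"].tolist() == [0.0, 0.0]
        np.testing.assert_allclose(table["weight"], [0.5, 0.5])

    def test_softmax_weights(self):
        loo_a = LooResult(0.0, 1.0, np.zeros(10), np.zeros(10), 10)
        loo_b = LooResult(-5.0, 1.0, np.full(10, -0.5), np.zeros(10), 10)
        table = compare_models({"better": loo_a, "worse": loo_b})
        assert table.index[0] == "better"
        assert table.loc["better", "delta_elpd"] == 0.0
        assert table.loc["better", "weight"] == pytest.approx(0.9933, abs=1e-4)
        assert table.loc["worse", "weight"] == pytest.approx(0.0067, abs=1e-4)

    def test_mismatched_observation_sets_rejected(self):
        loo_a = LooResult(0.0, 1.0, np.zeros(10), np.zeros(10), 10)
        loo_b = LooResult(0.0, 1.0, np.zeros(12), np.zeros(12), 12)
        with pytest.raises(ValueError):
            compare_models({"a": loo_a, "b": loo_b})


def test_additive_beats_linear_on_curved_data(rng, quick_mcmc):
    """A bell-shaped generating curve favors the additive model by > 2 SE."""
    basis = build_basis(10)
    x = np.arange(1, 11, dtype=float)
    curve = -0.4 * np.exp(-((x - 5.5) ** 2) / (2 * 2.5**2))
    scales = {"p1": 0.9, "p2": 1.0, "p3": 1.2, "p4": 1.1}
    df = _curve_data(rng, curve, scales, reps=60)
    linear = fit_hierarchical_linear(df, quick_mcmc)
    additive = fit_additive(df, basis, quick_mcmc)
    table = compare_models(
        {"linear": loo_elpd(linear), "additive": loo_elpd(additive)}
    )
    assert table.index[0] == "additive"
    delta = table.loc["linear", "delta_elpd"]
    assert -delta > 2 * table.loc["linear", "delta_se"]
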
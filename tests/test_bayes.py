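"""Mixed-model MCMC: determinism, recovery, curves and overlap reports."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from refmix.bayes import (
    LikelihoodCurve,
    MixedModelSpec,
    cell_label,
    compare_scenarios,
    contrast_weights,
    dcq_weights,
    fit_mixed_model,
    marginal_likelihood_curve,
    overlap_coefficient,
    run_variants,
)
from refmix.simulate import simulate_paired_mixtures

FAST = dict(n_chains=2, n_iter=1000, burn_in=300)


def single_cell_data(n=30, mean=25.0, sd=0.2, seed=0):
    """One fixed cell, one plate, one isolation: no random structure."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "analyte": "MIR-21",
            "source": "RNA_MIXTURE",
            "sample": "MIX1",
            "isolation_lab": "BRL",
            "isolation_rep": 1,
            "pcr_lab": "BDL",
            "plate": "P1",
            "well": [f"W{i}" for i in range(n)],
            "cq": rng.normal(mean, sd, n),
            "is_well_average": True,
        }
    )


@pytest.fixture(scope="module")
def paired_data():
    return simulate_paired_mixtures(
        {"MIR-21": (24.0, 25.0), "MIR-126": (28.0, 27.5)},
        seed=9,
    )


@pytest.fixture(scope="module")
def fitted(paired_data):
    return fit_mixed_model(paired_data, "MIR-21", seed=1, **FAST)


class TestFit:
    def test_same_seed_identical_draws(self, paired_data):
        a = fit_mixed_model(paired_data, "MIR-21", seed=5, **FAST)
        b = fit_mixed_model(paired_data, "MIR-21", seed=5, **FAST)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.sigmas["sigma_e"], b.sigmas["sigma_e"])

    def test_fixed_mean_recovery_without_random_structure(self):
        df = single_cell_data(n=30, mean=25.0, sd=0.2, seed=3)
        samples = fit_mixed_model(df, "MIR-21", seed=2, **FAST)
        draws = samples.functional_draws(
            {cell_label("RNA_MIXTURE", "BRL", "BDL", "MIX1"): 1.0}
        )
        assert abs(draws.mean() - 25.0) < 3 * draws.std()

    def test_plate_variance_covered_by_credible_interval(self):
        """Injected sigma_plate falls in the central 95% interval (calibration)."""
        covered = 0
        n_sims = 5
        for k in range(n_sims):
            df = simulate_paired_mixtures(
                {"MIR-21": (24.0, 25.0)},
                n_isolations=6, n_plates=4,
                sigma_plate=0.3, sigma_iso=0.1, sigma_well=0.1,
                seed=100 + k,
            )
            from refmix.data_model import collapse_wells

            collapsed = collapse_wells(df.drop(columns="at_ceiling"))
            samples = fit_mixed_model(collapsed, "MIR-21", seed=k, **FAST)
            lo, hi = np.quantile(samples.sigmas["sigma_plate"].ravel(), [0.025, 0.975])
            covered += int(lo <= 0.3 <= hi)
        assert covered >= n_sims - 1

    def test_unknown_analyte_raises(self, paired_data):
        with pytest.raises(ValueError):
            fit_mixed_model(paired_data, "MIR-999", seed=0, **FAST)

    def test_diagnostics_reported(self, fitted):
        assert {"parameter", "rhat", "ess"} <= set(fitted.diagnostics.columns)
        assert fitted.diagnostics["ess"].min() > 0


class TestCurves:
    def test_flat_prior_single_mean_matches_conjugate_profile(self):
        """Curve for one cell mean matches the closed-form normal posterior
        shape (flat prior, known-variance limit at large n)."""
        df = single_cell_data(n=200, mean=25.0, sd=0.3, seed=4)
        # The KDE's Monte-Carlo noise scales like N^(-2/5) (the Silverman
        # bandwidth shrinks as N^(-1/5)); ~3M draws are needed before the
        # sup-norm floor drops comfortably below the 1e-2 tolerance.
        samples = fit_mixed_model(df, "MIR-21", seed=6,
                                  n_chains=4, n_iter=750000, burn_in=1000)
        w = {cell_label("RNA_MIXTURE", "BRL", "BDL", "MIX1"): 1.0}
        curve = marginal_likelihood_curve(samples, w)
        y = df["cq"].to_numpy()
        n = len(y)
        # closed-form oracle: profiling the variance out of the normal
        # likelihood gives L(mu) ∝ (RSS0 + n(mu - ybar)^2)^(-n/2)
        rss0 = float(((y - y.mean()) ** 2).sum())
        ref = (1.0 + n * (curve.grid - y.mean()) ** 2 / rss0) ** (-n / 2)
        ref = ref / ref.max()
        assert np.max(np.abs(curve.likelihood - ref)) < 1e-2

    def test_curve_normalized_with_peak_at_mode(self, fitted):
        w = dcq_weights("RNA_MIXTURE", "BRL", "BDL")
        curve = marginal_likelihood_curve(fitted, w)
        assert curve.likelihood.max() == pytest.approx(1.0)
        # the grid is centred on the mode, so the peak sits mid-grid
        assert abs(np.argmax(curve.likelihood) - len(curve.grid) // 2) <= 2

    def test_zero_lab_effect_contrast_peaks_near_zero(self, fitted):
        w = contrast_weights(
            dcq_weights("RNA_MIXTURE", "BRL", "BDL"),
            dcq_weights("RNA_MIXTURE", "BRL", "BRL"),
        )
        curve = marginal_likelihood_curve(fitted, w)
        assert abs(curve.peak) < 0.1

    def test_translation_equivariance_of_dcq_curve(self, paired_data):
        """Adding a constant to every Cq leaves ΔCq curves unchanged."""
        shifted = paired_data.copy()
        shifted["cq"] += 3.0
        a = fit_mixed_model(paired_data, "MIR-21", seed=7, **FAST)
        b = fit_mixed_model(shifted, "MIR-21", seed=7, **FAST)
        w = dcq_weights("RNA_MIXTURE", "BRL", "BDL")
        assert np.allclose(a.functional_draws(w), b.functional_draws(w), atol=1e-9)

    def test_unknown_cell_in_functional_raises(self, fitted):
        with pytest.raises(KeyError):
            marginal_likelihood_curve(fitted, {"NOPE|X|Y|Z": 1.0})

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError):
            LikelihoodCurve("x", [0.0, -1.0], [1.0, 0.5])


class TestOverlap:
    def _triangle(self, center, half_width=1.0):
        g = np.linspace(center - half_width, center + half_width, 101)
        y = 1.0 - np.abs(g - center) / half_width
        return LikelihoodCurve("t", g, np.maximum(y, 1e-12))

    def test_identical_curves_overlap_one(self):
        c = self._triangle(0.0)
        assert overlap_coefficient(c, c) == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_curves_overlap_zero(self):
        assert overlap_coefficient(self._triangle(-5.0), self._triangle(5.0)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_shifted_gaussians_match_numeric_integration(self):
        g = np.linspace(-6, 8, 1401)
        a = LikelihoodCurve("a", g, np.exp(-0.5 * g**2))
        b = LikelihoodCurve("b", g, np.exp(-0.5 * (g - 2.0) ** 2))
        # closed form: two unit-SD gaussians 2 apart overlap 2*Phi(-1)
        expected = 2 * norm.cdf(-1.0)
        assert overlap_coefficient(a, b) == pytest.approx(expected, abs=1e-3)

    def test_compare_scenarios_report_structure(self):
        curves = [self._triangle(0.1), self._triangle(0.2), self._triangle(8.0)]
        report = compare_scenarios(curves)
        assert len(report["pairs"]) == 3
        far = [p for p in report["pairs"] if p["peak_b"] == pytest.approx(8.0)]
        assert all(p["separated"] for p in far)


class TestVariants:
    def test_single_variant_behaves_as_fit_plus_curve(self, paired_data):
        w = dcq_weights("RNA_MIXTURE", "BRL", "BDL")
        res = run_variants(paired_data, "MIR-21", w, variants=(1,), seed=3, **FAST)
        assert set(res["curves"]) == {1}
        assert res["peak_spread"] == 0.0

    def test_variants_reproducible_with_same_seed(self, paired_data):
        w = dcq_weights("RNA_MIXTURE", "BRL", "BDL")
        r1 = run_variants(paired_data, "MIR-21", w, variants=(1, 2), seed=3, **FAST)
        r2 = run_variants(paired_data, "MIR-21", w, variants=(1, 2), seed=3, **FAST)
        assert r1["peaks"] == r2["peaks"]

    def test_variant_specs(self):
        assert MixedModelSpec.for_variant(2).sd_prior == "halfcauchy"
        assert not MixedModelSpec.for_variant(3).isolation_random
        with pytest.raises(ValueError):
            MixedModelSpec.for_variant(4)
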
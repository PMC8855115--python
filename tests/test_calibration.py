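"""Global least-squares calibration: residuals, bounds, recovery, z-test."""

import numpy as np
import pytest

import fracrad as fr
from fracrad.model import FractionatedRadiationModel, compare_cell_lines
from tests.conftest import one_line_truth


@pytest.fixture(scope="module")
def small_noisefree():
    """Tiny noise-free 9L set (12 curves, both dose arms) at a coarse step."""
    truth = one_line_truth(
        fr.default_truth(noise_cv=0.0, replicates_per_condition=2, dt=0.05)
    )
    ds = fr.generate_dataset(truth, 21)
    line = truth.cell_lines["9L"]
    model = FractionatedRadiationModel(
        ds.curves, truth.generating_spec(), line.growth, line.kinetics, dt=0.05
    )
    theta_true = truth.generating_spec().vector_from_params(line.radiation)
    return truth, model, theta_true


class TestResiduals:
    def test_noise_free_self_consistency(self, small_noisefree):
        """Simulating the generator's own parameters reproduces the data."""
        _, model, theta_true = small_noisefree
        res = model.residuals(theta_true)
        assert res.size == model.n_obs
        assert np.abs(res).max() < 1e-6

    def test_single_point_curve_gives_length_one(self, spec3, growth_9l, kinetics):
        curve = fr.ConfluenceCurve("solo", "9L", "16x2", [0.0], [0.1])
        model = FractionatedRadiationModel([curve], fr.model_family()[6],
                                           growth_9l, kinetics, dt=0.1)
        theta = np.array([1.0, 3e-3, 0.04, 0.065])
        assert model.residuals(theta).shape == (1,)

    def test_ordering_invariant_to_input_permutation(self, small_noisefree, rng):
        truth, model, theta_true = small_noisefree
        line = truth.cell_lines["9L"]
        shuffled = list(model.curves)
        rng.shuffle(shuffled)
        model2 = FractionatedRadiationModel(
            shuffled, truth.generating_spec(), line.growth, line.kinetics, dt=0.05
        )
        np.testing.assert_array_equal(
            model.residuals(theta_true * 1.3), model2.residuals(theta_true * 1.3)
        )


class TestFit:
    def test_start_at_truth_converges_immediately(self, small_noisefree):
        _, model, theta_true = small_noisefree
        res = model.fit(start=theta_true, n_starts=1, max_nfev=100)
        assert res.converged
        assert res.rss < 1e-10

    def test_quick_noise_free_recovery(self, small_noisefree):
        _, model, theta_true = small_noisefree
        res = model.fit(n_starts=2, seed=5, max_nfev=400)
        np.testing.assert_allclose(res.params, theta_true, rtol=0.01)
        # intervals contain their estimates
        ci = res.conf_int()
        assert np.all(ci[:, 0] <= res.params) and np.all(res.params <= ci[:, 1])

    def test_bounds_respected_on_noisy_fit(self, noisy_fit_9l):
        assert np.all(noisy_fit_9l.params >= 0)
        assert noisy_fit_9l.rss == pytest.approx(
            float(noisy_fit_9l.resid @ noisy_fit_9l.resid)
        )

    def test_best_rss_not_worse_than_any_restart(self, noisy_fit_9l):
        endpoint_rss = [rec["rss"] for rec in noisy_fit_9l.start_records]
        assert noisy_fit_9l.rss <= min(endpoint_rss) + 1e-12

    def test_unbounded_lm_mode_agrees_on_noise_free_data(self, small_noisefree):
        """The soft-clipped Levenberg-Marquardt comparison mode reaches the
        same optimum as the bounded trust-region default when the optimum is
        interior."""
        _, model, theta_true = small_noisefree
        res = model.fit(start=theta_true * 1.2, n_starts=1, max_nfev=300,
                        method="lm")
        assert np.all(res.params >= 0)
        np.testing.assert_allclose(res.params, theta_true, rtol=1e-3)

    def test_fixed_seed_reproducible(self, small_noisefree):
        _, model, _ = small_noisefree
        a = model.fit(n_starts=2, seed=9, max_nfev=150)
        b = model.fit(n_starts=2, seed=9, max_nfev=150)
        np.testing.assert_array_equal(a.params, b.params)
        np.testing.assert_array_equal(a.resid, b.resid)

    def test_identifiability_audit_reports_correlations(self, noisy_fit_9l):
        corr = noisy_fit_9l.correlation_matrix()
        assert corr.shape == (6, 6)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        pairs = noisy_fit_9l.high_correlations(threshold=0.99)
        assert all(abs(c) > 0.99 for _, _, c in pairs)

    def test_summary_mentions_parameters(self, noisy_fit_9l):
        text = noisy_fit_9l.summary()
        for name in noisy_fit_9l.param_names:
            assert name in text


class TestCellLineComparison:
    @staticmethod
    def _stub(est, se, name="k_accum_D"):
        class Stub:
            param_names = [name]
            params = np.array([est])
            bse = np.array([se])

        return Stub()

    def test_identical_estimates_give_zero_z(self):
        z, p, sig = compare_cell_lines(self._stub(1.0, 0.1), self._stub(1.0, 0.1),
                                       "k_accum_D")
        assert z == 0.0 and p == pytest.approx(1.0) and not sig

    def test_boundary_at_normal_quantile(self):
        se = 0.1
        gap = 1.959963984540054 * np.sqrt(2) * se
        z, p, _ = compare_cell_lines(self._stub(1.0 + gap, se), self._stub(1.0, se),
                                     "k_accum_D")
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError):
            compare_cell_lines(self._stub(1.0, 0.1, "r"), self._stub(1.0, 0.1),
                               "k_accum_D")

    def test_threefold_dose_sensitivity_detected(self):
        """Two synthetic lines generated with 3x different late-death dose
        coefficients separate significantly at low noise."""
        import dataclasses

        base = one_line_truth(
            fr.default_truth(noise_cv=0.03, replicates_per_condition=2, dt=0.1)
        )
        line = base.cell_lines["9L"]
        sensitive = dataclasses.replace(
            line, radiation=dataclasses.replace(line.radiation, k_accum_D=6e-4)
        )
        truth_b = dataclasses.replace(base, cell_lines={"9L": sensitive})
        fits = []
        for truth, seed in ((base, 31), (truth_b, 32)):
            ds = fr.generate_dataset(truth, seed)
            model = FractionatedRadiationModel(
                ds.curves, truth.generating_spec(),
                truth.cell_lines["9L"].growth, truth.cell_lines["9L"].kinetics,
                dt=0.1,
            )
            fits.append(model.fit(n_starts=1, seed=1, max_nfev=200))
        z, p, sig = compare_cell_lines(fits[1], fits[0], "k_accum_D")
        assert sig and z > 0
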
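import numpy as np
import pytest

from trxss import kinetics, synthetic_data
from trxss.kinetics import SequentialKineticModel
from trxss.models import DifferenceDataset

MODEL = SequentialKineticModel(tau1=2e-6, tau2=0.25)


class TestSequentialConcentrations:
    def test_intermediate_peaks_at_one_fast_lifetime(self):
        conc = kinetics.sequential_concentrations(MODEL, np.array([2e-6]))
        # tau1 << tau2 so C1(tau1) ~ 1 - 1/e
        assert conc[0, 0] == pytest.approx(0.6321, abs=1e-4)
        assert conc[1, 0] < 1e-4

    def test_early_time_limit_is_zero(self):
        conc = kinetics.sequential_concentrations(MODEL, np.array([1e-12]))
        assert np.abs(conc).max() < 1e-6

    @pytest.mark.parametrize(
        "tau1,tau2", [(2e-6, 0.25), (1e-5, 1e-4), (0.3, 0.5)]
    )
    def test_sum_identity(self, tau1, tau2):
        """C1 + C2 = 1 - exp(-t/tau1), an algebraic identity of the scheme."""
        model = SequentialKineticModel(tau1, tau2)
        t = np.logspace(-8, 1, 400)
        conc = kinetics.sequential_concentrations(model, t)
        assert np.abs(conc.sum(axis=0) - (1 - np.exp(-t / tau1))).max() < 1e-12

    def test_concentrations_bounded(self):
        t = np.logspace(-9, 2, 1000)
        conc = kinetics.sequential_concentrations(MODEL, t)
        assert np.all(conc >= -1e-15)
        assert np.all(conc <= 1 + 1e-15)

    def test_equal_time_constants_rejected(self):
        with pytest.raises(ValueError, match="degenerate|tau"):
            SequentialKineticModel(1e-3, 1e-3)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            kinetics.sequential_concentrations(MODEL, np.array([-1.0, 1.0]))


class TestSmoothPolynomial:
    def _dataset(self, values, q=None):
        q = np.linspace(0, 1, values.shape[0]) if q is None else q
        return DifferenceDataset(q, np.arange(1, values.shape[1] + 1, dtype=float), values)

    def test_low_degree_polynomial_is_reproduced_exactly(self):
        q = np.linspace(0, 1, 50)
        curve = 1.0 - 2.0 * q + 3.0 * q**2 - 0.5 * q**3
        ds = self._dataset(curve[:, None])
        out = kinetics.smooth_polynomial(ds, degree=3)
        assert np.abs(out.dI - ds.dI).max() < 1e-9

    def test_noise_variance_reduced(self, rng):
        noise = rng.normal(size=(101, 1))
        ds = self._dataset(noise)
        out = kinetics.smooth_polynomial(ds, degree=10)
        assert out.dI.var() < ds.dI.var()

    def test_full_degree_interpolates(self, rng):
        values = rng.normal(size=(12, 1))
        ds = self._dataset(values)
        out = kinetics.smooth_polynomial(ds, degree=11)
        assert np.abs(out.dI - ds.dI).max() < 1e-6

    def test_degree_too_high_rejected(self, rng):
        ds = self._dataset(rng.normal(size=(10, 1)))
        with pytest.raises(ValueError):
            kinetics.smooth_polynomial(ds, degree=10)


class TestFitDecomposition:
    def test_noise_free_recovery(self, truth_bundle):
        truth = truth_bundle[0]
        times = np.logspace(-7, np.log10(5.0), 25)
        ds = synthetic_data.generate_dataset(truth, times, noise_sigma=0.0)
        decomp = kinetics.fit_decomposition(ds)
        assert decomp.model.tau1 == pytest.approx(truth.tau1, rel=0.01)
        assert decomp.model.tau2 == pytest.approx(truth.tau2, rel=0.01)
        # basis recovered up to the absorbed turnover scale
        for got, want in (
            (decomp.basis_int, truth.basis_int),
            (decomp.basis_fin, truth.basis_fin),
        ):
            scale = got.I @ want.I / (want.I @ want.I)
            resid = np.abs(got.I - scale * want.I).max() / np.abs(want.I).max()
            assert resid < 1e-6
        assert decomp.converged

    def test_exact_columns_give_zero_residual(self, truth_bundle):
        truth = truth_bundle[0]
        times = np.array([1e-6, 1e-4, 0.1, 2.0])
        ds = synthetic_data.generate_dataset(truth, times, noise_sigma=0.0)
        decomp = kinetics.fit_decomposition(ds)
        assert decomp.residual_norm < 1e-8 * np.abs(ds.dI).max() * len(times)

    def test_invariant_under_joint_rescaling(self, truth_bundle):
        truth = truth_bundle[0]
        times = np.logspace(-7, np.log10(5.0), 25)
        ds = synthetic_data.generate_dataset(truth, times, noise_sigma=0.02, seed=4)
        scaled = DifferenceDataset(ds.q, ds.times, 5.0 * ds.dI)
        d1 = kinetics.fit_decomposition(ds)
        d2 = kinetics.fit_decomposition(scaled)
        assert d2.model.tau1 == pytest.approx(d1.model.tau1, rel=1e-6)
        assert d2.model.tau2 == pytest.approx(d1.model.tau2, rel=1e-6)
        assert np.allclose(d2.basis_int.I, 5.0 * d1.basis_int.I, rtol=1e-6)

    def test_recovery_error_grows_with_noise(self, truth_bundle):
        """Same noise realization, scaled: recovery degrades monotonically."""
        truth = truth_bundle[0]
        times = np.logspace(-7, np.log10(5.0), 25)
        errs = []
        for level in (0.0, 0.05, 0.3):
            ds = synthetic_data.generate_dataset(
                truth, times, noise_sigma=level, seed=11
            )
            decomp = kinetics.fit_decomposition(ds)
            errs.append(
                abs(np.log(decomp.model.tau1 / truth.tau1))
                + abs(np.log(decomp.model.tau2 / truth.tau2))
            )
        assert errs[0] <= errs[1] + 1e-9 <= errs[2] + 2e-9

    def test_too_few_delays_rejected(self, truth_bundle):
        truth = truth_bundle[0]
        ds = synthetic_data.generate_dataset(truth, np.array([1e-6, 1.0]), noise_sigma=0.0)
        with pytest.raises(ValueError):
            kinetics.fit_decomposition(ds)


class TestReconstruct:
    def test_roundtrip_on_noise_free_data(self, truth_bundle):
        truth = truth_bundle[0]
        times = np.logspace(-7, np.log10(5.0), 25)
        ds = synthetic_data.generate_dataset(truth, times, noise_sigma=0.0)
        decomp = kinetics.fit_decomposition(ds)
        rec = kinetics.reconstruct(decomp, times)
        assert np.abs(rec.dI - ds.dI).max() < 1e-8 * np.abs(ds.dI).max()

    def test_long_time_limit_is_final_basis(self, truth_bundle):
        truth = truth_bundle[0]
        times = np.logspace(-7, np.log10(5.0), 25)
        ds = synthetic_data.generate_dataset(truth, times, noise_sigma=0.0)
        decomp = kinetics.fit_decomposition(ds)
        rec = kinetics.reconstruct(decomp, np.array([1e6]))
        assert np.allclose(rec.dI[:, 0], decomp.basis_fin.I, atol=1e-10)


class TestFitMonoexponential:
    def test_exact_trace_recovery(self):
        t = np.linspace(1e-7, 1e-5, 20)
        y = 1.0 * np.exp(-t / 2e-6)
        fit = kinetics.fit_monoexponential(t, y)
        assert fit.converged
        assert fit.tau == pytest.approx(2e-6, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)
        assert abs(fit.offset) < 1e-9

    def test_constant_trace_flagged(self):
        t = np.linspace(1e-7, 1e-5, 20)
        fit = kinetics.fit_monoexponential(t, np.full(20, 3.0))
        assert not fit.converged

    def test_noisy_median_recovery(self):
        t = np.linspace(1e-7, 1.2e-5, 50)
        taus = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.exp(-t / 2e-6) + 0.3 + rng.normal(0, 0.05, len(t))
            fit = kinetics.fit_monoexponential(t, y)
            taus.append(fit.tau)
        assert np.median(taus) == pytest.approx(2e-6, rel=0.10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kinetics.fit_monoexponential(np.array([1.0, 2.0]), np.array([1.0, 0.5]))
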
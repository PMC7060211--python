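"""Decay model correctness (against independent quadrature), fit recovery,
model nesting, support planes and MCMC reproducibility."""

import numpy as np
import pytest
from scipy.integrate import quad

from fretdyn import decay_fit as dfit
from fretdyn import photon_sim

TAU_D = 4.0
R0 = 52.0


def _model(**kw):
    base = dict(fractions=[1.0], distances_A=[45.0], widths_A=[8.0],
                x_donly=0.0, donor_amplitudes=[1.0], donor_taus_ns=[TAU_D],
                r0_A=R0)
    base.update(kw)
    return dfit.DistanceModel(**{k: np.asarray(v) if isinstance(v, list)
                                 else v for k, v in base.items()})


class TestForwardModel:
    def test_delta_distance_at_r0_halves_lifetime(self):
        """p(R) = delta at R0 makes k_FRET = 1/tau_D, so F(t) = e^{-t/2ns}
        and the steady-state transfer efficiency is 1/2."""
        m = _model(widths_A=[1e-5])
        m = _model(distances_A=[R0], widths_A=[1e-5])
        t = np.linspace(0.0, 20.0, 400)
        f = dfit.fret_induced_donor_decay(m, t)
        assert np.allclose(f, np.exp(-t / 2.0), rtol=1e-6)
        # steady-state E = 1 - integral(F)/tau_D
        e = 1.0 - np.trapezoid(f, t) / TAU_D
        assert e == pytest.approx(0.5, abs=1e-3)

    def test_narrow_width_limit_matches_delta(self):
        t = np.linspace(0.0, 20.0, 200)
        narrow = dfit.fret_induced_donor_decay(
            _model(distances_A=[48.0], widths_A=[1e-4]), t)
        k = (R0 / 48.0) ** 6 / TAU_D
        delta = np.exp(-t / TAU_D) * np.exp(-k * t)
        assert np.allclose(narrow, delta, rtol=1e-6)

    def test_gaussian_distance_against_adaptive_quadrature(self):
        """441-point fixed quadrature vs scipy adaptive integration."""
        m = _model(distances_A=[45.0], widths_A=[8.0])
        t_check = np.array([0.3, 1.7, 5.0, 12.0])
        f = dfit.fret_induced_donor_decay(m, t_check)

        norm = quad(lambda r: np.exp(-0.5 * ((r - 45) / 8) ** 2), 1,
                    np.inf)[0]

        def oracle(tv):
            val = quad(lambda r: np.exp(-0.5 * ((r - 45) / 8) ** 2)
                       * np.exp(-tv / TAU_D)
                       * np.exp(-tv * (R0 / r) ** 6 / TAU_D),
                       1, np.inf)[0]
            return val / norm

        expect = np.array([oracle(tv) for tv in t_check])
        assert np.allclose(f, expect, rtol=1e-4)

    def test_monotone_nonincreasing_after_peak(self):
        t = np.arange(512) * (25.0 / 512)
        irf = dfit.gaussian_irf(t, mean_ns=1.0, width_ns=0.05)
        ds = dfit.DecayDataset(da=dfit.DecayCurve(t, np.ones(512)), irf=irf)
        m = _model(fractions=[0.6, 0.4], distances_A=[40.0, 55.0],
                   widths_A=[5.0, 5.0])
        curve = dfit.model_curve(ds, m, amplitude=1.0)
        peak = np.argmax(curve)
        assert np.all(np.diff(curve[peak:]) <= 1e-12)

    def test_donor_mixture_spectrum(self):
        m = _model(distances_A=[500.0], widths_A=[1.0],
                   donor_amplitudes=[0.6, 0.4], donor_taus_ns=[2.0, 5.0])
        t = np.linspace(0, 10, 50)
        f = dfit.fret_induced_donor_decay(m, t)
        expect = 0.6 * np.exp(-t / 2.0) + 0.4 * np.exp(-t / 5.0)
        assert np.allclose(f, expect, rtol=1e-4)

    def test_invalid_models_rejected(self):
        with pytest.raises(ValueError):
            _model(r0_A=-5.0)
        with pytest.raises(ValueError):
            _model(fractions=[0.5, 0.2], distances_A=[40, 50],
                   widths_A=[5, 5])
        with pytest.raises(ValueError):
            dfit.DistanceModel(fractions=[1.0], distances_A=[45.0],
                               widths_A=[6.0], donor_amplitudes=np.array([]),
                               donor_taus_ns=np.array([]))


@pytest.fixture(scope="module")
def one_component_dataset():
    truth = _model(distances_A=[45.7], widths_A=[12.0], x_donly=0.1)
    t = np.arange(512) * (25.0 / 512)
    ds = photon_sim.simulate_decay_dataset(truth, t, 3_000_000, seed=5)
    return truth, ds


@pytest.fixture(scope="module")
def three_component_dataset():
    truth = dfit.DistanceModel(
        fractions=[0.44, 0.38, 0.18], distances_A=[58.0, 47.0, 36.0],
        widths_A=[3.0, 3.0, 3.0], x_donly=0.1,
        donor_taus_ns=[TAU_D], r0_A=R0)
    t = np.arange(256) * (25.0 / 256)
    ds = photon_sim.simulate_decay_dataset(truth, t, 10_000_000, seed=100)
    return truth, ds


class TestFitting:
    def test_one_component_round_trip(self, one_component_dataset):
        truth, ds = one_component_dataset
        res = dfit.fit_decays_global([ds], 1, donor_amplitudes=[1.0],
                                     donor_taus_ns=[TAU_D], n_restarts=2,
                                     seed=0)
        assert res.success
        assert res.distances_A[0, 0] == pytest.approx(45.7, abs=0.5)
        assert res.widths_A[0, 0] == pytest.approx(12.0, abs=1.0)
        assert 0.8 < res.chi2r_global < 1.2

    def test_donly_lifetime_from_reference(self, one_component_dataset):
        _, ds = one_component_dataset
        amps, taus = dfit._donly_spectrum(ds)
        assert taus[0] == pytest.approx(TAU_D, rel=0.05)

    def test_one_component_fit_of_three_inflates_width(
            self, three_component_dataset):
        """A single Gaussian forced onto three-conformer data reports an
        unphysically broad distribution -- the rejection signature."""
        truth, ds = three_component_dataset
        res = dfit.fit_decays_global([ds], 1, donor_amplitudes=[1.0],
                                     donor_taus_ns=[TAU_D], n_restarts=2,
                                     seed=0)
        assert res.widths_A[0, 0] > 2.0 * truth.widths_A.max()
        res3 = dfit.fit_decays_global([ds], 3, donor_amplitudes=[1.0],
                                      donor_taus_ns=[TAU_D], n_restarts=2,
                                      seed=0, max_nfev=150)
        assert res3.chi2r_global < res.chi2r_global

    def test_nested_component_with_zero_fraction(self, one_component_dataset):
        """Clamping an extra component to zero fraction reproduces the
        1-component chi2 (model nesting)."""
        truth, ds = one_component_dataset
        res1 = dfit.fit_decays_global([ds], 1, donor_amplitudes=[1.0],
                                      donor_taus_ns=[TAU_D], n_restarts=1,
                                      start=[truth])
        start2 = dfit.DistanceModel(
            fractions=[1.0 - 1e-9, 1e-9],
            distances_A=[truth.distances_A[0], 60.0],
            widths_A=[truth.widths_A[0], 6.0], x_donly=truth.x_donly,
            donor_taus_ns=[TAU_D], r0_A=R0)
        res2 = dfit.fit_decays_global(
            [ds], 2, start=[start2], donor_amplitudes=[1.0],
            donor_taus_ns=[TAU_D],
            fixed={("fraction", 1): 0.0, ("distance", 0, 1): 60.0,
                   ("width", 0, 1): 6.0})
        assert res2.chi2r_global == pytest.approx(res1.chi2r_global,
                                                  rel=1e-3)

    def test_global_sharing_reduces_free_parameters(self):
        """Sharing fractions across K datasets saves 2(K-1) parameters
        for a 3-component model."""
        m = [_model(fractions=[0.5, 0.3, 0.2], distances_A=[40, 50, 60],
                    widths_A=[5, 5, 5]) for _ in range(3)]
        shared = dfit._Packer(3, 3, m, fit_donly=True)
        independent = 3 * dfit._Packer(3, 1, m[:1], fit_donly=True).size
        assert independent - shared.size == 2 * (3 - 1)

    def test_rejects_bad_requests(self, one_component_dataset):
        _, ds = one_component_dataset
        with pytest.raises(ValueError):
            dfit.fit_decays_global([ds], 0)
        with pytest.raises(ValueError):
            dfit.fit_decays_global([], 1)


class TestSupportPlane:
    def test_minimum_near_truth_on_scan(self, one_component_dataset):
        truth, ds = one_component_dataset
        res = dfit.fit_decays_global([ds], 1, start=[truth],
                                     donor_amplitudes=[1.0],
                                     donor_taus_ns=[TAU_D])
        grid = np.linspace(44.9, 46.5, 9)
        sp = dfit.support_plane_scan([ds], res, ("distance", 0, 0), grid,
                                     max_nfev=100)
        best_grid = grid[np.argmin(sp.chi2r)]
        step = grid[1] - grid[0]
        assert abs(best_grid - 45.7) <= step + 0.25
        assert sp.ci[0] <= res.distances_A[0, 0] <= sp.ci[1]
        assert sp.dr_minus >= 0 and sp.dr_plus >= 0

    def test_grid_missing_optimum_flags_warning(self, one_component_dataset):
        truth, ds = one_component_dataset
        res = dfit.fit_decays_global([ds], 1, start=[truth],
                                     donor_amplitudes=[1.0],
                                     donor_taus_ns=[TAU_D])
        with pytest.warns(UserWarning, match="does not cover"):
            sp = dfit.support_plane_scan([ds], res, ("distance", 0, 0),
                                         np.linspace(55.0, 60.0, 3),
                                         max_nfev=40)
        assert not sp.grid_covers_optimum


class TestMCMC:
    def test_chains_reproducible_and_consistent(self, one_component_dataset):
        truth, ds = one_component_dataset
        res = dfit.fit_decays_global([ds], 1, start=[truth],
                                     donor_amplitudes=[1.0],
                                     donor_taus_ns=[TAU_D])
        s1, acc, flag = dfit.mcmc_uncertainty(ds, res.models[0],
                                              n_samples=250, seed=9)
        s2, _, _ = dfit.mcmc_uncertainty(ds, res.models[0],
                                         n_samples=250, seed=9)
        assert np.array_equal(s1, s2)
        assert not flag
        # posterior for the mean distance concentrates near the fit value
        names = dfit._Packer(1, 1, [res.models[0]]).names
        col = [i for i, n in enumerate(names) if n[0] == "log_r"][0]
        assert np.mean(s1[:, col]) == pytest.approx(res.distances_A[0, 0],
                                                    abs=0.5)
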
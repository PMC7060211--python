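"""Burst selection determinism/locality, FRET indicators, FRET-line
geometry and the bootstrap histogram comparison."""

import numpy as np
import pytest
from scipy import stats

from fretdyn import burst_mfd, photon_sim
from fretdyn.burst_mfd import Burst, BurstParams, Corrections
from fretdyn.photon_sim import GREEN_P, PhotonStream, RED_P


def _stream_from_times(times_s, detectors=None, sync_s=32e-9,
                       micro=None, n_channels=4096):
    times_s = np.asarray(times_s)
    order = np.argsort(times_s, kind="stable")
    times_s = times_s[order]
    det = (np.zeros(len(times_s), dtype=np.int8) if detectors is None
           else np.asarray(detectors, dtype=np.int8)[order])
    mic = (np.zeros(len(times_s), dtype=np.int32) if micro is None
           else np.asarray(micro, dtype=np.int32)[order])
    return PhotonStream(
        macrotimes=(times_s / sync_s).astype(np.int64),
        microtimes=mic, detectors=det, sync_period_s=sync_s,
        micro_channel_width_ns=32.0 / n_channels * 1e0,
        n_channels=n_channels,
        meta={"duration_s": float(times_s[-1]) if len(times_s) else 0.0})


class TestSelectBursts:
    def test_empty_stream(self):
        s = _stream_from_times([])
        assert burst_mfd.select_bursts(s) == []

    def test_sparse_background_yields_no_bursts(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 5.0, int(2e3 * 5)))  # 2 kHz for 5 s
        s = _stream_from_times(t)
        assert burst_mfd.select_bursts(s) == []

    def test_single_transit_one_burst(self):
        """A dense 1 ms cluster of 200 photons inside sparse background is
        found as exactly one burst covering the transit."""
        rng = np.random.default_rng(1)
        bg = rng.uniform(0, 2.0, 1000)
        transit = 1.0 + np.sort(rng.uniform(0, 1e-3, 200))
        s = _stream_from_times(np.concatenate([bg, transit]))
        bursts = burst_mfd.select_bursts(s)
        assert len(bursts) == 1
        b = bursts[0]
        assert b.t_start_s == pytest.approx(1.0, abs=2e-4)
        assert b.stop_index - b.start_index >= 190

    def test_concatenation_locality(self):
        """Appending a far-away stream does not change the bursts found in
        the first part (selection is local within the window)."""
        rng = np.random.default_rng(2)
        part1 = np.concatenate([rng.uniform(0, 1.0, 300),
                                0.5 + np.sort(rng.uniform(0, 1e-3, 150))])
        part2 = 10.0 + np.concatenate(
            [rng.uniform(0, 1.0, 300),
             0.2 + np.sort(rng.uniform(0, 5e-4, 300))])
        s1 = _stream_from_times(part1)
        s12 = _stream_from_times(np.concatenate([part1, part2]))
        b1 = burst_mfd.select_bursts(s1)
        b12 = burst_mfd.select_bursts(s12)
        assert len(b12) == len(b1) + 1
        assert b12[0].t_start_s == pytest.approx(b1[0].t_start_s, abs=1e-9)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        t = np.concatenate([rng.uniform(0, 1.0, 2000),
                            0.3 + np.sort(rng.uniform(0, 2e-3, 400))])
        s = _stream_from_times(t)
        counts = [len(burst_mfd.select_bursts(
            s, BurstParams(min_neighbors=nl))) for nl in (5, 10, 20, 40)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestBurstIndicators:
    def test_efficiency_from_counts(self):
        """75 red / 25 green photons, ideal corrections: E = 0.75."""
        det = np.array([GREEN_P] * 25 + [RED_P] * 75, dtype=np.int8)
        t = np.linspace(0, 1e-3, 100)
        s = _stream_from_times(t, detectors=det)
        b = Burst(start_index=0, stop_index=100, t_start_s=0.0,
                  duration_s=1e-3, n_green=25, n_red=75)
        b = burst_mfd.burst_indicators(s, b, Corrections())
        assert b.efficiency == pytest.approx(0.75)

    def test_lifetime_mle_within_crlb(self):
        """500 i.i.d. exp(2 ns) micro-times: MLE within 3 tau/sqrt(n)."""
        rng = np.random.default_rng(4)
        n_chan, rep = 4096, 32.0
        width = rep / n_chan
        tau_draw = rng.exponential(2.0, 500) + 2.0   # 2 ns offset, delta IRF
        micro = np.clip((tau_draw / width).astype(np.int32), 0, n_chan - 1)
        det = np.full(500, GREEN_P, dtype=np.int8)
        s = _stream_from_times(np.linspace(0, 1e-3, 500), detectors=det,
                               micro=micro)
        b = Burst(start_index=0, stop_index=500, t_start_s=0.0,
                  duration_s=1e-3, n_green=500, n_red=0)
        b = burst_mfd.burst_indicators(s, b, Corrections(),
                                       irf_mean_ns=2.0,
                                       fit_range_ns=(2.0, 30.0))
        assert abs(b.tau_ns - 2.0) < 3 * 2.0 / np.sqrt(500)

    def test_donor_only_burst(self, single_state_bursts):
        cfg, _ = single_state_bursts
        d_cfg = photon_sim.SimConfig(
            duration_s=3.0, n_molecules=1, brightness_khz=(100.0,),
            efficiencies=(0.0,), initial_positions_um=np.zeros(3),
            immobile=True, seed=41)
        s = photon_sim.simulate_photon_stream(d_cfg)
        bursts = burst_mfd.select_bursts(s)
        assert bursts
        b = burst_mfd.burst_indicators(s, bursts[0], Corrections())
        assert b.efficiency == pytest.approx(0.0, abs=0.02)
        assert b.tau_ns == pytest.approx(4.0, rel=0.1)

    def test_invalid_after_correction_flagged(self):
        s = _stream_from_times(np.linspace(0, 1e-3, 60))
        b = Burst(start_index=0, stop_index=60, t_start_s=0.0,
                  duration_s=1e-3, n_green=30, n_red=30)
        b = burst_mfd.burst_indicators(
            s, b, Corrections(bg_green_khz=100.0, bg_red_khz=100.0))
        assert not b.valid


class TestFretLines:
    def test_zero_linker_static_line_is_exact(self):
        line = burst_mfd.static_fret_line(
            4.0, r0_A=52.0, sigma_link_A=0.0,
            r_grid_A=np.linspace(15.0, 8 * 52.0, 400))
        e_expect = 1.0 - line.tau_f_ns / 4.0
        assert np.allclose(line.efficiency, e_expect, atol=1e-12)
        # passes through (tau_D0, 0) in the far-distance limit
        assert line.efficiency_at(4.0) == pytest.approx(0.0, abs=1e-4)

    def test_linker_broadening_bends_line_right(self):
        """With sigma_link > 0, <tau>_F exceeds <tau>_x so the line lies
        right of the ideal diagonal at intermediate E."""
        line = burst_mfd.static_fret_line(4.0, r0_A=52.0, sigma_link_A=6.0)
        ideal_tau = 4.0 * (1.0 - line.efficiency)
        mid = (line.efficiency > 0.2) & (line.efficiency < 0.8)
        assert np.all(line.tau_f_ns[mid] >= ideal_tau[mid] - 1e-9)
        assert np.any(line.tau_f_ns[mid] > ideal_tau[mid] + 0.05)

    def test_dynamic_line_moment_point(self):
        """Equal-fraction mixture of tau' = 1 and 3 ns: moments give
        <tau>_F = 2.5 ns and E = 0.5, which must lie on the line."""
        line = burst_mfd.dynamic_fret_line(1.0, 3.0, 4.0)
        # hand oracle: <tau>_F = sum x tau^2 / sum x tau, E = 1 - <tau>_x/tau0
        tau_f = (0.5 * 1 + 0.5 * 9) / (0.5 * 1 + 0.5 * 3)
        assert tau_f == 2.5
        assert line.efficiency_at(2.5) == pytest.approx(0.5, abs=1e-4)

    def test_dynamic_line_endpoints(self):
        line = burst_mfd.dynamic_fret_line(1.0, 3.0, 4.0)
        assert line.efficiency_at(1.0) == pytest.approx(1 - 1 / 4, abs=1e-9)
        assert line.efficiency_at(3.0) == pytest.approx(1 - 3 / 4, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            burst_mfd.static_fret_line(4.0, sigma_link_A=-1.0)
        with pytest.raises(ValueError):
            burst_mfd.dynamic_fret_line(5.0, 1.0, 4.0)


def _fake_bursts(e_values, tau_values):
    return [Burst(start_index=0, stop_index=1, t_start_s=0.0,
                  duration_s=1e-3, n_green=50, n_red=50,
                  efficiency=e, tau_ns=t)
            for e, t in zip(e_values, tau_values)]


class TestCompareHistograms:
    def test_identical_sets_p_one(self):
        rng = np.random.default_rng(5)
        bursts = _fake_bursts(rng.uniform(0, 1, 200),
                              rng.uniform(0.5, 3.5, 200))
        out = burst_mfd.compare_histograms(bursts, bursts, n_boot=200,
                                           seed=0)
        assert out["p_e"] == 1.0 and out["p_2d"] == 1.0

    def test_small_sets_flagged(self):
        rng = np.random.default_rng(6)
        a = _fake_bursts(rng.uniform(0, 1, 10), rng.uniform(0, 4, 10))
        out = burst_mfd.compare_histograms(a, a)
        assert out["p_e"] is None and out["flag"]

    def test_different_generators_rejected(self):
        rng = np.random.default_rng(7)
        a = _fake_bursts(rng.normal(0.3, 0.05, 400),
                         rng.normal(2.8, 0.2, 400))
        b = _fake_bursts(rng.normal(0.7, 0.05, 400),
                         rng.normal(1.2, 0.2, 400))
        out = burst_mfd.compare_histograms(a, b, n_boot=300, seed=1)
        assert out["p_e"] < 0.01 and out["p_2d"] < 0.01

    def test_null_pvalues_roughly_uniform(self):
        """Same-generator sets give p ~ Uniform(0,1) (KS at alpha=0.01)."""
        rng = np.random.default_rng(8)
        ps = []
        for rep in range(60):
            e1, t1 = rng.uniform(0, 1, 150), rng.uniform(0.5, 3.5, 150)
            e2, t2 = rng.uniform(0, 1, 600), rng.uniform(0.5, 3.5, 600)
            out = burst_mfd.compare_histograms(
                _fake_bursts(e1, t1), _fake_bursts(e2, t2),
                n_boot=150, seed=rep)
            ps.append(out["p_e"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01
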
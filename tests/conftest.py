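"""Shared fixtures: session-scoped simulations reused across test modules
(photon streams and dye clouds are the expensive pieces)."""

import numpy as np
import pytest

from fretdyn import burst_mfd, ffcs, photon_sim
from fretdyn.kinetics import RateNetwork
from fretdyn.pipeline import make_distance_fixture, toy_two_domain_structure


@pytest.fixture(scope="session")
def two_state_stream():
    """20 s two-state exchange stream, k_f + k_b = 1/(10 us)."""
    net = RateNetwork(50.0, 50.0, 0.0, 0.0)
    cfg = photon_sim.SimConfig(
        duration_s=20.0, n_molecules=10,
        brightness_khz=(120.0, 120.0), efficiencies=(0.2, 0.8),
        background_khz=(0.0, 0.0), seed=21)
    stream = photon_sim.simulate_photon_stream(cfg, net)
    return cfg, net, stream


@pytest.fixture(scope="session")
def two_state_filters(two_state_stream):
    cfg, net, stream = two_state_stream
    taus = cfg.state_donor_taus()
    pats = np.stack([
        ffcs.species_pattern(cfg.efficiencies[0], taus[0],
                             cfg.acceptor_tau_ns, cfg.n_microtime_channels,
                             cfg.rep_period_ns),
        ffcs.species_pattern(cfg.efficiencies[1], taus[1],
                             cfg.acceptor_tau_ns, cfg.n_microtime_channels,
                             cfg.rep_period_ns),
    ])
    return ffcs.build_filters(pats, ffcs.measured_pattern(stream),
                              n_detectors=4)


@pytest.fixture(scope="session")
def two_state_curves(two_state_stream, two_state_filters):
    _, _, stream = two_state_stream
    return ffcs.correlate_filtered(stream, two_state_filters, bin_s=1e-6)


def _burst_set(cfg, network, seed):
    cfg = photon_sim.SimConfig(**{**cfg.__dict__, "seed": seed})
    stream = photon_sim.simulate_photon_stream(cfg, network)
    corr = burst_mfd.Corrections(bg_green_khz=cfg.background_khz[0],
                                 bg_red_khz=cfg.background_khz[1])
    bursts = [burst_mfd.burst_indicators(stream, b, corr)
              for b in burst_mfd.select_bursts(stream)]
    return [b for b in bursts
            if b.valid and np.isfinite(b.tau_ns) and b.tau_ns > 0]


@pytest.fixture(scope="session")
def single_state_bursts():
    """Static molecules in one conformer (E = 0.5); centroid test bed."""
    cfg = photon_sim.SimConfig(
        duration_s=40.0, n_molecules=12,
        brightness_khz=(250.0,), efficiencies=(0.5,),
        background_khz=(0.3, 0.2), seed=31)
    return cfg, _burst_set(cfg, None, 31)


@pytest.fixture(scope="session")
def fast_exchange_bursts():
    """Two-state exchange at t_R = 5 us, far below the ~0.5 ms transit."""
    net = RateNetwork(100.0, 100.0, 0.0, 0.0)
    cfg = photon_sim.SimConfig(
        duration_s=40.0, n_molecules=12,
        brightness_khz=(250.0, 250.0), efficiencies=(0.25, 0.75),
        background_khz=(0.3, 0.2), seed=32)
    return cfg, _burst_set(cfg, net, 32)


@pytest.fixture(scope="session")
def toy_structures():
    return {name: toy_two_domain_structure(angle, name=name)
            for name, angle in
            (("open", 55.0), ("ajar", 35.0), ("closed", 15.0))}


@pytest.fixture(scope="session")
def toy_distance_set(toy_structures):
    return make_distance_fixture(toy_structures, seed=3, grid_spacing_A=1.5)
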
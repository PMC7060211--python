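"""Brownian-dynamics photon-stream simulation for confocal smFRET.

Molecules diffuse through a 3D Gaussian detection volume in a periodic box
while hopping between conformational states of a linear kinetic network;
detected photons carry a macro-time (sync ticks), a TCSPC micro-time channel
and a detector id, the same record structure as a TTTR measurement.  State
switching inside a diffusion step is resolved exactly by thinning, so
microsecond kinetics are not aliased by the (larger) diffusion time step.

The module also Poisson-samples ensemble TCSPC histograms from a distance-
distribution model, standing in for high-photon-count cuvette measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import RateNetwork

__all__ = [
    "SimConfig",
    "StateTrajectory",
    "PhotonStream",
    "simulate_state_trajectory",
    "simulate_photon_stream",
    "simulate_decay_histogram",
    "simulate_decay_dataset",
]

# detector ids
GREEN_P, GREEN_S, RED_P, RED_S = 0, 1, 2, 3
GREEN = (GREEN_P, GREEN_S)
RED = (RED_P, RED_S)


@dataclass
class SimConfig:
    """Study conditions of a simulated single-molecule measurement.

    Defaults emulate a typical confocal MFD experiment on a mid-size
    protein: ~0.1 nm diffusing molecules at ~100 kHz peak molecular
    brightness, 0.54 ms diffusion time through a 0.5 x 2.0 um 3D Gaussian
    focus, 32 ns excitation period on 4096 TCSPC channels.
    """

    duration_s: float = 10.0
    box_half_um: tuple = (2.5, 2.5, 5.0)
    w_xy_um: float = 0.5
    w_z_um: float = 2.0
    diffusion_um2_per_ms: float = 0.115   # t_diff = w_xy^2/(4D) = 0.54 ms
    n_molecules: int = 12
    brightness_khz: tuple = (100.0,)      # total detected rate at focus, per state
    efficiencies: tuple = (0.5,)          # FRET efficiency per state
    tau_da_ns: tuple | None = None        # donor lifetime per state; default tau_D0*(1-E)
    donor_amplitudes: tuple = (1.0,)
    donor_taus_ns: tuple = (4.0,)
    acceptor_tau_ns: float = 1.0
    donor_only_fraction: float = 0.0
    donly_brightness_khz: float | None = None
    background_khz: tuple = (0.0, 0.0)    # (green, red) totals
    crosstalk_alpha: float = 0.0
    gamma: float = 1.0
    rep_period_ns: float = 32.0
    n_microtime_channels: int = 4096
    irf_width_ns: float = 0.25
    irf_mean_ns: float = 2.0
    initial_positions_um: np.ndarray | None = None
    immobile: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w_xy_um <= 0 or self.w_z_um <= 0:
            raise ValueError("detection-volume radii must be positive")
        if self.rep_period_ns <= 0:
            raise ValueError("repetition period must be positive")
        if min(self.brightness_khz) < 0:
            raise ValueError("brightness must be non-negative")
        if not all(0.0 <= e <= 1.0 for e in self.efficiencies):
            raise ValueError("FRET efficiencies must be in [0, 1]")
        if not (0.0 <= self.donor_only_fraction <= 1.0):
            raise ValueError("donor-only fraction must be in [0, 1]")
        if len(self.brightness_khz) != len(self.efficiencies):
            raise ValueError("brightness and efficiency tables differ in length")
        # >= 99.9% of emission must fit in the repetition period
        tau_max = max(max(self.donor_taus_ns), self.acceptor_tau_ns)
        if self.rep_period_ns < self.irf_mean_ns + 6.9 * tau_max:
            raise ValueError("repetition period too short for the lifetime spectrum")

    @property
    def tau_d0_ns(self) -> float:
        a = np.asarray(self.donor_amplitudes, float)
        t = np.asarray(self.donor_taus_ns, float)
        return float(np.sum(a * t) / np.sum(a))

    def state_donor_taus(self) -> np.ndarray:
        if self.tau_da_ns is not None:
            return np.asarray(self.tau_da_ns, float)
        e = np.asarray(self.efficiencies, float)
        return self.tau_d0_ns * np.maximum(1.0 - e, 1e-3)

    @property
    def time_step_s(self) -> float:
        """Diffusion step such that the rms displacement is <= w_xy/20."""
        d = self.diffusion_um2_per_ms * 1e3  # um^2/s
        if d <= 0:
            return 1e-5
        return (self.w_xy_um / 20.0) ** 2 / (2.0 * d)


@dataclass
class StateTrajectory:
    """Piecewise-constant state path: (state, entry time, dwell)."""

    states: np.ndarray          # int state ids
    entry_s: np.ndarray         # strictly increasing entry times
    dwell_s: np.ndarray
    exit_rates_per_ms: np.ndarray

    def state_at(self, t_s: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.entry_s, t_s, side="right") - 1
        return self.states[np.clip(idx, 0, len(self.states) - 1)]


@dataclass
class PhotonStream:
    """Time-tagged photon records, the lingua franca of the pipeline."""

    macrotimes: np.ndarray      # int64 sync ticks, non-decreasing
    microtimes: np.ndarray      # int TCSPC channel
    detectors: np.ndarray       # int detector id
    sync_period_s: float
    micro_channel_width_ns: float
    n_channels: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.macrotimes) and np.any(np.diff(self.macrotimes) < 0):
            raise ValueError("macro-times must be non-decreasing")
        if len(self.microtimes) and int(np.max(self.microtimes)) >= self.n_channels:
            raise ValueError("micro-time channel out of range")

    def __len__(self) -> int:
        return len(self.macrotimes)

    @property
    def times_s(self) -> np.ndarray:
        return self.macrotimes * self.sync_period_s

    @property
    def duration_s(self) -> float:
        return float(self.meta.get("duration_s",
                     self.times_s[-1] if len(self) else 0.0))


# ---------------------------------------------------------------------------
# state trajectories (Gillespie)
# ---------------------------------------------------------------------------

def simulate_state_trajectory(
    network: RateNetwork, duration_s: float, seed=0,
    start_state: int | None = None,
) -> StateTrajectory:
    """Continuous-time Markov path over the network for ``duration_s``.

    Dwell times in state i are Exponential(1/k_i) with k_i the total exit
    rate; the successor is drawn proportionally to the outgoing rates.  An
    absorbing state terminates the path (its final dwell is clipped to the
    remaining duration).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = network.rate_matrix()  # ms^-1
    n = K.shape[0]
    exit_rates = -np.diag(K)                       # ms^-1
    exit_rates_s = exit_rates * 1e3                # s^-1
    if start_state is None:
        x = network.chain_equilibrium()
        start_state = int(rng.choice(n, p=x))

    rates4 = (network.k12, network.k21, network.k23, network.k32)
    fast3 = (all(r > 0 for r in rates4) and not network.is_cyclic)
    fast2 = (network.k12 > 0 and network.k21 > 0
             and network.k23 == 0 and network.k32 == 0
             and not network.is_cyclic and start_state in (0, 1))
    fast = fast3 or fast2
    margin = 1.25
    for _ in range(8):
        if fast3:
            states = _linear_chain_states(network, exit_rates_s, duration_s,
                                          start_state, rng, margin)
        elif fast2:
            mean_dwell = 0.5 * (1.0 / exit_rates_s[0] + 1.0 / exit_rates_s[1])
            n_est = int(duration_s / mean_dwell * margin) + 64
            states = np.empty(n_est, dtype=np.int64)
            states[0::2] = start_state
            states[1::2] = 1 - start_state   # strict alternation
        else:
            states = _generic_chain_states(K, exit_rates_s, duration_s,
                                           start_state, rng)
        states = np.asarray(states, dtype=np.int64)
        rates = exit_rates_s[states]
        with np.errstate(divide="ignore"):
            dwell = np.where(rates > 0,
                             rng.exponential(1.0, size=len(states))
                             / np.maximum(rates, 1e-300),
                             np.inf)
        entry = np.concatenate([[0.0], np.cumsum(dwell)[:-1]])
        covered = entry[-1] + dwell[-1] >= duration_s
        if covered or not fast:
            break
        margin *= 2.0  # vectorized estimate fell short; redraw longer
    keep = entry < duration_s
    states, entry, dwell = states[keep], entry[keep], dwell[keep]
    dwell = np.minimum(dwell, duration_s - entry)
    return StateTrajectory(states=states, entry_s=entry, dwell_s=dwell,
                           exit_rates_per_ms=exit_rates)


def _linear_chain_states(network, exit_rates_s, duration_s, start, rng, margin):
    """Vectorized embedded chain for the all-rates-positive linear 3-chain.

    From C2 the walker chooses C1 or C3; from C1 or C3 it returns to C2
    deterministically, so every other step is C2 and the intervening states
    are i.i.d. Bernoulli draws -- no python-level event loop needed.
    """
    # visit-frequency-weighted mean dwell of the embedded chain
    p_to_c1 = network.k21 / (network.k21 + network.k23)
    mean_dwell = 0.5 * (1.0 / exit_rates_s[1]
                        + p_to_c1 / exit_rates_s[0]
                        + (1.0 - p_to_c1) / exit_rates_s[2])
    n_est = int(duration_s / mean_dwell * margin) + 64
    states = np.empty(n_est, dtype=np.int64)
    if start == 1:
        states[0::2] = 1
        states[1::2] = np.where(rng.random(len(states[1::2])) < p_to_c1, 0, 2)
    else:
        states[1::2] = 1
        states[2::2] = np.where(rng.random(len(states[2::2])) < p_to_c1, 0, 2)
        states[0] = start
    return states


def _generic_chain_states(K, exit_rates_s, duration_s, start, rng):
    n = K.shape[0]
    jump_p = []
    for i in range(n):
        out = K[:, i].copy()
        out[i] = 0.0
        tot = out.sum()
        jump_p.append(out / tot if tot > 0 else None)
    states = [start]
    t = 0.0
    while True:
        s = states[-1]
        if exit_rates_s[s] <= 0:
            break  # absorbing
        t += rng.exponential(1.0 / exit_rates_s[s])
        if t >= duration_s:
            break
        states.append(int(rng.choice(n, p=jump_p[s])))
        if len(states) > 50_000_000:
            raise RuntimeError("trajectory too long; rates/duration unreasonable")
    return states


# ---------------------------------------------------------------------------
# photon stream
# ---------------------------------------------------------------------------

def simulate_photon_stream(
    config: SimConfig,
    network: RateNetwork | None = None,
    seed: int | None = None,
    return_truth: bool = False,
) -> PhotonStream:
    """Diffusion + kinetics + photophysics -> sorted photon records.

    Each molecule gets a deterministic child seed of the master seed.  Per
    diffusion step the molecule position (and hence the Gaussian detection
    weight) is frozen; candidate photons are drawn at the maximum state
    brightness and accepted by the instantaneous state (thinning), which
    resolves state switching exactly within the step.
    """
    seed = config.seed if seed is None else seed
    n_states = len(config.brightness_khz)
    if network is not None and len(network.labels) < n_states:
        raise ValueError("network inconsistent with per-state brightness table")

    master = np.random.SeedSequence(seed)
    children = master.spawn(config.n_molecules + 1)
    bg_rng = np.random.default_rng(children[-1])

    rep_s = config.rep_period_ns * 1e-9
    all_t, all_micro, all_det = [], [], []
    truth_state = []

    q = np.asarray(config.brightness_khz, float) * 1e3          # Hz
    e = np.asarray(config.efficiencies, float)
    tau_da = config.state_donor_taus()

    n_donly = int(round(config.donor_only_fraction * config.n_molecules))
    q_d0 = (config.donly_brightness_khz * 1e3
            if config.donly_brightness_khz is not None else float(np.mean(q)))

    for im in range(config.n_molecules):
        rng = np.random.default_rng(children[im])
        donly = im < n_donly
        if donly or n_states == 1 or network is None:
            traj = None
            state0 = 0
        else:
            traj = simulate_state_trajectory(network, config.duration_s, seed=rng)
            state0 = int(traj.states[0])
        t, micro, det, st = _simulate_molecule(
            config, rng, traj, state0, q, e, tau_da, donly, q_d0)
        all_t.append(t)
        all_micro.append(micro)
        all_det.append(det)
        truth_state.append(st)

    # background: homogeneous Poisson per colour, uniform micro-times
    for colour, rate_khz in zip((GREEN, RED), config.background_khz):
        n_bg = bg_rng.poisson(rate_khz * 1e3 * config.duration_s)
        if n_bg == 0:
            continue
        t = bg_rng.uniform(0.0, config.duration_s, n_bg)
        micro_ns = bg_rng.uniform(0.0, config.rep_period_ns, n_bg)
        det = bg_rng.choice(colour, size=n_bg)
        all_t.append(t)
        all_micro.append(micro_ns)
        all_det.append(det)
        truth_state.append(np.full(n_bg, -1, dtype=np.int8))

    t = np.concatenate(all_t) if all_t else np.empty(0)
    micro_ns = np.concatenate(all_micro) if all_micro else np.empty(0)
    det = np.concatenate(all_det) if all_det else np.empty(0, dtype=np.int8)
    st = np.concatenate(truth_state) if truth_state else np.empty(0, dtype=np.int8)

    order = np.argsort(t, kind="stable")
    t, micro_ns, det, st = t[order], micro_ns[order], det[order], st[order]

    macro = np.floor(t / rep_s).astype(np.int64)
    width_ns = config.rep_period_ns / config.n_microtime_channels
    chan = np.floor(np.mod(micro_ns, config.rep_period_ns) / width_ns).astype(np.int32)
    chan = np.clip(chan, 0, config.n_microtime_channels - 1)

    meta = {"duration_s": config.duration_s, "seed": seed,
            "rep_period_ns": config.rep_period_ns}
    if return_truth:
        meta["true_state"] = st
    return PhotonStream(
        macrotimes=macro, microtimes=chan, detectors=det.astype(np.int8),
        sync_period_s=rep_s, micro_channel_width_ns=width_ns,
        n_channels=config.n_microtime_channels, meta=meta,
    )


def _simulate_molecule(config, rng, traj, state0, q, e, tau_da, donly, q_d0):
    box = np.asarray(config.box_half_um, float)
    dt = config.time_step_s
    n_steps = int(np.ceil(config.duration_s / dt))
    sigma = np.sqrt(2.0 * config.diffusion_um2_per_ms * 1e3 * dt)

    if config.initial_positions_um is not None:
        pos0 = np.asarray(config.initial_positions_um, float)
        pos0 = pos0 if pos0.ndim == 1 else pos0[rng.integers(len(pos0))]
    else:
        pos0 = rng.uniform(-box, box)

    q_max = q_d0 if donly else float(np.max(q))
    out_t, out_micro, out_det, out_state = [], [], [], []
    chunk = 1 << 20
    pos = pos0.copy()
    for start in range(0, n_steps, chunk):
        m = min(chunk, n_steps - start)
        if config.immobile or sigma == 0.0:
            xyz = np.tile(pos, (m, 1))
        else:
            steps = rng.normal(0.0, sigma, size=(m, 3))
            xyz = pos + np.cumsum(steps, axis=0)
            # periodic wrap keeps the total molecule number constant
            xyz = np.mod(xyz + box, 2.0 * box) - box
            pos = xyz[-1].copy()
        w = np.exp(-2.0 * (xyz[:, 0] ** 2 + xyz[:, 1] ** 2) / config.w_xy_um ** 2
                   - 2.0 * xyz[:, 2] ** 2 / config.w_z_um ** 2)
        lam = q_max * w * dt
        n_ph = rng.poisson(lam)
        total = int(n_ph.sum())
        if total == 0:
            continue
        step_idx = np.repeat(np.arange(m), n_ph)
        t_ph = (start + step_idx) * dt + rng.uniform(0.0, dt, total)
        t_ph = t_ph[t_ph < config.duration_s]
        total = len(t_ph)
        if total == 0:
            continue
        if donly:
            state = np.zeros(total, dtype=np.int8)
            accept = np.ones(total, dtype=bool)
            p_red = np.zeros(total)
        else:
            state = (traj.state_at(t_ph).astype(np.int8) if traj is not None
                     else np.full(total, state0, dtype=np.int8))
            accept = rng.random(total) < q[state] / q_max
            p_red = e[state] + (1.0 - e[state]) * config.crosstalk_alpha
        t_ph, state, p_red = t_ph[accept], state[accept], p_red[accept]
        total = len(t_ph)
        if total == 0:
            continue
        is_red = rng.random(total) < p_red
        micro = np.empty(total)
        if donly:
            micro[:] = _donor_spectrum_draw(config, rng, total)
        else:
            micro[:] = rng.exponential(tau_da[state])
            micro[is_red] += rng.exponential(config.acceptor_tau_ns,
                                             size=int(is_red.sum()))
        micro += rng.normal(config.irf_mean_ns, config.irf_width_ns, total)
        micro = np.mod(micro, config.rep_period_ns)
        pol = rng.integers(0, 2, total)
        det = np.where(is_red, RED_P, GREEN_P) + pol
        out_t.append(t_ph)
        out_micro.append(micro)
        out_det.append(det.astype(np.int8))
        out_state.append(state)

    if not out_t:
        z = np.empty(0)
        return z, z, z.astype(np.int8), z.astype(np.int8)
    return (np.concatenate(out_t), np.concatenate(out_micro),
            np.concatenate(out_det), np.concatenate(out_state))


def _donor_spectrum_draw(config, rng, n):
    a = np.asarray(config.donor_amplitudes, float)
    a = a / a.sum()
    taus = np.asarray(config.donor_taus_ns, float)
    which = rng.choice(len(a), size=n, p=a)
    return rng.exponential(taus[which])


# ---------------------------------------------------------------------------
# ensemble decay histograms
# ---------------------------------------------------------------------------

def simulate_decay_histogram(
    model, irf, total_counts: int, seed: int = 0,
    sampling: str = "poisson", background_per_channel: float = 0.0,
):
    """Poisson/multinomial-sample a TCSPC histogram from a distance model.

    The expected curve is the FRET-induced donor decay reconvolved with the
    supplied IRF and scaled to ``total_counts``.  Ground truth is recorded
    in the dataset metadata for recovery tests.
    """
    from . import decay_fit as dfit

    if total_counts < 1:
        raise ValueError("total_counts must be >= 1")
    if np.sum(irf.counts) <= 0:
        raise ValueError("IRF has zero mass")
    rng = np.random.default_rng(seed)
    t0 = irf.t_ns - irf.t_ns[0]
    f = dfit.fret_induced_donor_decay(model, t0)
    irf_n = irf.counts / irf.counts.sum()
    expected = np.convolve(irf_n, f)[: len(f)]
    expected = expected / expected.sum()
    if sampling == "multinomial":
        counts = rng.multinomial(int(total_counts), expected).astype(float)
    elif sampling == "poisson":
        counts = rng.poisson(expected * total_counts).astype(float)
    else:
        raise ValueError("sampling must be 'multinomial' or 'poisson'")
    if background_per_channel > 0:
        counts += rng.poisson(background_per_channel, size=len(counts))
    da = dfit.DecayCurve(irf.t_ns, counts)
    ds = dfit.DecayDataset(
        da=da, irf=irf, background=background_per_channel,
        meta={"truth": {
            "fractions": model.fractions.tolist(),
            "distances_A": model.distances_A.tolist(),
            "widths_A": model.widths_A.tolist(),
            "x_donly": model.x_donly,
        }, "seed": seed},
    )
    return ds


def simulate_decay_dataset(
    model, t_ns: np.ndarray, total_counts: int, donly_counts: int | None = None,
    irf_mean_ns: float = 2.0, irf_width_ns: float = 0.25, seed: int = 0,
):
    """Convenience trio: DA histogram + DOnly reference + Gaussian IRF."""
    from . import decay_fit as dfit
    from dataclasses import replace as _replace

    irf = dfit.gaussian_irf(t_ns, irf_mean_ns, irf_width_ns)
    ds = simulate_decay_histogram(model, irf, total_counts, seed=seed)
    if donly_counts is None:
        donly_counts = max(total_counts // 3, 1)
    d0_model = _replace(model, x_donly=1.0)
    d0 = simulate_decay_histogram(d0_model, irf, donly_counts, seed=seed + 1)
    ds.donly = d0.da
    return ds
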
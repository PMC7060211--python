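"""Single-molecule burst analysis and multiparameter (MFD) histograms.

Bursts are transits of individual molecules through the focus, selected by
a sliding-window neighbour criterion on the photon arrival times.  Each
burst yields an intensity-based FRET efficiency E and a fluorescence-
averaged donor lifetime <tau_D(A)>_F; populations in the 2D (tau, E) plane
are read against the static FRET-line (single conformer, linker-broadened)
and dynamic FRET-lines (mixtures of two exchanging states averaged within
a burst).  A bootstrap chi-square distance compares experimental and
simulated burst histograms, the model-discrimination step that picks
between competing kinetic solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .photon_sim import GREEN, RED, PhotonStream

__all__ = [
    "Burst",
    "BurstParams",
    "Corrections",
    "FretLine",
    "select_bursts",
    "burst_indicators",
    "fret_lines",
    "static_fret_line",
    "dynamic_fret_line",
    "compare_histograms",
    "bursts_to_frame",
]


@dataclass
class BurstParams:
    """Sliding-window burst search settings (typical MFD defaults)."""

    window_s: float = 120e-6
    min_neighbors: int = 10
    min_photons: int = 60


@dataclass
class Corrections:
    gamma: float = 1.0              # detection-efficiency ratio g_R/g_G
    alpha: float = 0.0              # spectral crosstalk green -> red
    bg_green_khz: float = 0.0
    bg_red_khz: float = 0.0


@dataclass
class Burst:
    start_index: int
    stop_index: int                 # exclusive
    t_start_s: float
    duration_s: float
    n_green: int
    n_red: int
    f_green: float = np.nan         # background/crosstalk-corrected signals
    f_red: float = np.nan
    efficiency: float = np.nan
    tau_ns: float = np.nan
    valid: bool = True
    flags: list = field(default_factory=list)


def select_bursts(stream: PhotonStream, params: BurstParams | None = None) -> list[Burst]:
    """Sliding-window selection: keep photons with >= L neighbours within a
    centred window T, merge consecutive kept photons, drop small bursts."""
    params = params or BurstParams()
    n = len(stream)
    if n == 0:
        return []
    t = stream.times_s
    half = params.window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    neighbors = hi - lo - 1
    keep = neighbors >= params.min_neighbors
    bursts: list[Burst] = []
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return []
    # split where the kept-photon index run breaks
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [idx.size - 1]])
    det = stream.detectors
    for a, b in zip(starts, stops):
        i0, i1 = int(idx[a]), int(idx[b]) + 1
        if i1 - i0 < params.min_photons:
            continue
        d = det[i0:i1]
        bursts.append(Burst(
            start_index=i0, stop_index=i1,
            t_start_s=float(t[i0]),
            duration_s=float(max(t[i1 - 1] - t[i0], stream.sync_period_s)),
            n_green=int(np.isin(d, GREEN).sum()),
            n_red=int(np.isin(d, RED).sum()),
        ))
    return bursts


def burst_indicators(
    stream: PhotonStream,
    burst: Burst,
    corrections: Corrections | None = None,
    irf_mean_ns: float = 2.0,
    fit_range_ns: tuple[float, float] | None = None,
) -> Burst:
    """Fill in (E, <tau_D(A)>_F) for one burst.

    E = F_A / (F_A + gamma F_G) after background subtraction and crosstalk
    correction; the lifetime is a maximum-likelihood single-exponential fit
    to the green micro-times over a window that excludes the IRF rise.
    """
    c = corrections or Corrections()
    bg_g = c.bg_green_khz * 1e3 * burst.duration_s
    bg_r = c.bg_red_khz * 1e3 * burst.duration_s
    f_g = burst.n_green - bg_g
    f_r = burst.n_red - bg_r - c.alpha * f_g
    burst.f_green, burst.f_red = f_g, f_r
    tot = f_r + c.gamma * f_g
    if tot <= 0:
        burst.valid = False
        burst.flags.append("non-positive corrected signal")
        return burst
    burst.efficiency = f_r / tot
    if not (-0.1 <= burst.efficiency <= 1.1):
        burst.flags.append("efficiency outside [-0.1, 1.1]")

    det = stream.detectors[burst.start_index:burst.stop_index]
    micro = stream.microtimes[burst.start_index:burst.stop_index]
    green = np.isin(det, GREEN)
    t_ns = micro[green] * stream.micro_channel_width_ns
    rep_ns = stream.n_channels * stream.micro_channel_width_ns
    if fit_range_ns is None:
        fit_range_ns = (irf_mean_ns + 0.5, rep_ns)
    # expected uniform-background photons inside the fit window dilute the
    # exponential; fold them into the likelihood as a flat component
    n_bg = c.bg_green_khz * 1e3 * burst.duration_s \
        * (fit_range_ns[1] - fit_range_ns[0]) / rep_ns
    n_sig = max(int(green.sum()) - n_bg, 1.0)
    bg_fraction = min(n_bg / (n_bg + n_sig), 0.9)
    burst.tau_ns = _mle_lifetime(t_ns, fit_range_ns, bg_fraction)
    return burst


def _mle_lifetime(t_ns: np.ndarray, fit_range_ns: tuple[float, float],
                  bg_fraction: float = 0.0) -> float:
    """MLE of tau for an exponential truncated to [t0, t1], optionally
    mixed with a known flat-background fraction."""
    t0, t1 = fit_range_ns
    sel = (t_ns >= t0) & (t_ns < t1)
    if sel.sum() < 5:
        return np.nan
    x = t_ns[sel] - t0
    window = t1 - t0
    xbar = float(np.mean(x))
    if xbar >= window / 2 * 0.999:      # flat: lifetime >> window
        return np.inf

    if bg_fraction <= 1e-6:
        def gap(tau):
            with np.errstate(over="ignore"):
                return tau - window / np.expm1(window / tau) - xbar

        try:
            return float(optimize.brentq(gap, 1e-3, 1e3))
        except ValueError:
            return np.nan

    b = bg_fraction

    def nll(tau):
        norm = -np.expm1(-window / tau) * tau
        dens = (1.0 - b) * np.exp(-x / tau) / norm + b / window
        return -float(np.sum(np.log(np.maximum(dens, 1e-300))))

    res = optimize.minimize_scalar(nll, bounds=(1e-2, 1e2), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# FRET-lines
# ---------------------------------------------------------------------------

@dataclass
class FretLine:
    kind: str                       # "static" | "dynamic"
    tau_f_ns: np.ndarray            # parametric points
    efficiency: np.ndarray
    tau_d0_ns: float
    sigma_link_A: float = 0.0
    endpoints_ns: tuple | None = None

    def efficiency_at(self, tau_f_ns: float) -> float:
        order = np.argsort(self.tau_f_ns)
        return float(np.interp(tau_f_ns, self.tau_f_ns[order],
                               self.efficiency[order]))


def static_fret_line(
    tau_d0_ns: float, r0_A: float = 52.0, sigma_link_A: float = 6.0,
    r_grid_A: np.ndarray | None = None,
) -> FretLine:
    """Locus of single conformers in the (<tau>_F, E) plane.

    Each point is a Gaussian linker-broadened distance distribution centred
    at R with width sigma_link; E = 1 - <tau>_x/tau_D0 while the abscissa is
    the fluorescence-weighted <tau>_F = <tau^2>/<tau>.  With sigma_link = 0
    the line collapses to E = 1 - tau/tau_D0.
    """
    if sigma_link_A < 0:
        raise ValueError("sigma_link must be >= 0")
    if tau_d0_ns <= 0:
        raise ValueError("tau_d0 must be positive")
    if r_grid_A is None:
        r_grid_A = np.linspace(0.3 * r0_A, 2.5 * r0_A, 200)
    tau_f = np.empty(len(r_grid_A))
    eff = np.empty(len(r_grid_A))
    for i, rc in enumerate(r_grid_A):
        if sigma_link_A == 0.0:
            tau = tau_d0_ns / (1.0 + (r0_A / rc) ** 6)
            tau_x, tau_sq = tau, tau * tau
        else:
            r = np.linspace(max(1.0, rc - 5 * sigma_link_A),
                            rc + 5 * sigma_link_A, 201)
            p = np.exp(-0.5 * ((r - rc) / sigma_link_A) ** 2)
            p /= p.sum()
            tau = tau_d0_ns / (1.0 + (r0_A / r) ** 6)
            tau_x = float(p @ tau)
            tau_sq = float(p @ tau ** 2)
        tau_f[i] = tau_sq / tau_x
        eff[i] = 1.0 - tau_x / tau_d0_ns
    return FretLine("static", tau_f, eff, tau_d0_ns, sigma_link_A)


def dynamic_fret_line(
    tau1_ns: float, tau2_ns: float, tau_d0_ns: float, n_points: int = 200,
) -> FretLine:
    """Mixing line between two exchanging states with species lifetimes
    tau'_1, tau'_2: eliminating the species fraction from the first two
    lifetime moments gives <tau>_x = tau1 tau2 / (tau1 + tau2 - <tau>_F)
    and E = 1 - <tau>_x / tau_D0."""
    if not (0 < tau1_ns < tau_d0_ns and 0 < tau2_ns < tau_d0_ns):
        raise ValueError("endpoint lifetimes must lie in (0, tau_D0)")
    lo, hi = sorted((tau1_ns, tau2_ns))
    tau_f = np.linspace(lo, hi, n_points)
    tau_x = tau1_ns * tau2_ns / (tau1_ns + tau2_ns - tau_f)
    eff = 1.0 - tau_x / tau_d0_ns
    return FretLine("dynamic", tau_f, eff, tau_d0_ns,
                    endpoints_ns=(tau1_ns, tau2_ns))


def fret_lines(tau_d0_ns: float, endpoint_taus_ns: tuple | None = None,
               sigma_link_A: float = 6.0, r0_A: float = 52.0) -> FretLine:
    """Static line by default; dynamic line when two endpoint state
    lifetimes are given."""
    if endpoint_taus_ns is None:
        return static_fret_line(tau_d0_ns, r0_A=r0_A, sigma_link_A=sigma_link_A)
    t1, t2 = endpoint_taus_ns
    return dynamic_fret_line(t1, t2, tau_d0_ns)


# ---------------------------------------------------------------------------
# histogram comparison
# ---------------------------------------------------------------------------

def _hist2d(e, tau, bins_e, bins_tau):
    h, _, _ = np.histogram2d(e, tau, bins=[bins_e, bins_tau])
    return h


def _chi2_distance(h1, h2):
    p = h1 / max(h1.sum(), 1)
    q = h2 / max(h2.sum(), 1)
    denom = p + q
    mask = denom > 0
    return float(0.5 * np.sum((p[mask] - q[mask]) ** 2 / denom[mask]))


def compare_histograms(
    experimental: list[Burst],
    simulated: list[Burst],
    tau_d0_ns: float = 4.0,
    n_bins: int = 61,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Bootstrap p-values for the chi-square distance between burst
    histograms (1D in E, 1D in <tau>_F, and the 2D joint histogram).

    The null distribution resamples both sets from their pooled union
    (a bootstrap analogue of a permutation test), so p ~ Uniform(0,1)
    when both sets come from the same generator and p ~ 0 when the
    kinetic model disagrees with the data.
    """
    e_exp = np.array([b.efficiency for b in experimental if b.valid])
    e_sim = np.array([b.efficiency for b in simulated if b.valid])
    t_exp = np.array([b.tau_ns for b in experimental if b.valid])
    t_sim = np.array([b.tau_ns for b in simulated if b.valid])
    if len(e_exp) < 50 or len(e_sim) < 50:
        return {"p_e": None, "p_tau": None, "p_2d": None,
                "flag": "fewer than 50 bursts"}
    rng = np.random.default_rng(seed)
    bins_e = np.linspace(-0.1, 1.1, n_bins + 1)
    bins_t = np.linspace(0.0, tau_d0_ns + 0.5, n_bins + 1)
    t_exp = np.clip(np.nan_to_num(t_exp, nan=-1), -1, bins_t[-1] - 1e-9)
    t_sim = np.clip(np.nan_to_num(t_sim, nan=-1), -1, bins_t[-1] - 1e-9)

    n_e, n_s = len(e_exp), len(e_sim)
    pool_e = np.concatenate([e_exp, e_sim])
    pool_t = np.concatenate([t_exp, t_sim])

    out = {}
    for key, (x_exp, x_sim, pool, bins) in {
        "p_e": (e_exp, e_sim, pool_e, bins_e),
        "p_tau": (t_exp, t_sim, pool_t, bins_t),
    }.items():
        h_exp = np.histogram(x_exp, bins=bins)[0].astype(float)
        h_sim = np.histogram(x_sim, bins=bins)[0].astype(float)
        obs = _chi2_distance(h_exp, h_sim)
        null = np.empty(n_boot)
        for b in range(n_boot):
            ra = rng.choice(pool, size=n_e, replace=True)
            rb = rng.choice(pool, size=n_s, replace=True)
            null[b] = _chi2_distance(
                np.histogram(ra, bins=bins)[0].astype(float),
                np.histogram(rb, bins=bins)[0].astype(float))
        out[key] = float(np.mean(null >= obs))

    h_exp = _hist2d(e_exp, t_exp, bins_e, bins_t)
    h_sim = _hist2d(e_sim, t_sim, bins_e, bins_t)
    obs = _chi2_distance(h_exp, h_sim)
    null = np.empty(n_boot)
    n_pool = n_e + n_s
    for b in range(n_boot):
        ia = rng.integers(0, n_pool, size=n_e)
        ib = rng.integers(0, n_pool, size=n_s)
        null[b] = _chi2_distance(
            _hist2d(pool_e[ia], pool_t[ia], bins_e, bins_t),
            _hist2d(pool_e[ib], pool_t[ib], bins_e, bins_t))
    out["p_2d"] = float(np.mean(null >= obs))
    out["flag"] = ""
    return out


def mfd_histogram2d(bursts: list[Burst], tau_d0_ns: float = 4.0,
                    n_bins: int = 61):
    """2D (E, <tau>_F) MFD histogram on the standard binning; returns
    (grid, e_edges, tau_edges).  The grid is a dense array suitable for
    plain-text export with numpy.savetxt."""
    e = np.array([b.efficiency for b in bursts if b.valid])
    tau = np.array([b.tau_ns for b in bursts if b.valid])
    bins_e = np.linspace(-0.1, 1.1, n_bins + 1)
    bins_t = np.linspace(0.0, tau_d0_ns + 0.5, n_bins + 1)
    tau = np.clip(np.nan_to_num(tau, nan=-1.0), -1.0, bins_t[-1] - 1e-9)
    h, _, _ = np.histogram2d(e, tau, bins=[bins_e, bins_t])
    return h, bins_e, bins_t


def bursts_to_frame(bursts: list[Burst]) -> pd.DataFrame:
    """Burst table in the CSV layout used by the CLI."""
    return pd.DataFrame({
        "burst_id": np.arange(len(bursts)),
        "t_start_ms": [b.t_start_s * 1e3 for b in bursts],
        "duration_ms": [b.duration_s * 1e3 for b in bursts],
        "F_D": [b.f_green for b in bursts],
        "F_A": [b.f_red for b in bursts],
        "E": [b.efficiency for b in bursts],
        "tau_ns": [b.tau_ns for b in bursts],
    })
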
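"""Filtered fluorescence correlation spectroscopy (fFCS).

Species leave a characteristic pattern in the TCSPC micro-time (and
detector) dimension of a photon stream.  Weighted least-squares filters
turn those patterns into per-photon weights whose correlation functions
are species-selective: auto-correlations (sACF) of one species, and
cross-correlations (sCCF) between two, whose anti-correlated kinetic terms
expose exchange relaxation times far below the diffusion time.  Fitting
the diffusion x kinetics model to the four curves jointly recovers the
relaxation-time spectrum of the conformational network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .photon_sim import PhotonStream

__all__ = [
    "FilterSet",
    "CorrCurve",
    "build_filters",
    "correlate_filtered",
    "fit_correlations",
    "expected_microtime_pattern",
    "ftest_n_relax",
]


@dataclass
class FilterSet:
    """Per-species weights over the flattened (detector, micro-channel) axis."""

    weights: np.ndarray          # (n_species, n_det * n_chan)
    patterns: np.ndarray         # the species patterns used (same layout)
    total: np.ndarray            # measured total histogram
    amplitudes: np.ndarray       # species photon numbers in the total
    n_detectors: int
    n_channels: int

    def photon_weights(self, stream: PhotonStream, species: int) -> np.ndarray:
        flat = stream.detectors.astype(np.int64) * self.n_channels \
            + stream.microtimes
        return self.weights[species, flat]


def build_filters(patterns: np.ndarray, total: np.ndarray,
                  n_detectors: int = 1) -> FilterSet:
    """Unbiased species filters w = (M^T D M)^-1 M^T D, D = diag(1/total).

    ``patterns`` holds one normalized micro-time histogram per species
    (rows); ``total`` is the measured histogram over the same flattened
    (detector, channel) axis.  Applying the species-i filter to the
    expected pure-species-j histogram returns delta_ij times the species-j
    photon number -- the defining unbiasedness property.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    total = np.asarray(total, dtype=float)
    n_sp, n_flat = patterns.shape
    if total.shape != (n_flat,):
        raise ValueError("total histogram does not match the pattern layout")
    retained = total > 0
    p = patterns[:, retained] / patterns.sum(axis=1, keepdims=True)
    t = total[retained]

    # scale patterns to species amplitudes (least-squares decomposition of
    # the total), so filtered sums count photons
    amps, *_ = np.linalg.lstsq(p.T, t, rcond=None)
    m = p * amps[:, None]                    # (n_sp, n_flat_kept)
    d = 1.0 / t
    gram = (m * d) @ m.T                     # M^T D M
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        pair = _most_collinear_pair(p)
        raise np.linalg.LinAlgError(
            f"species patterns are linearly dependent (worst pair {pair})")
    w_kept = np.linalg.solve(gram, m * d)    # (n_sp, n_flat_kept)
    # scale rows so the filtered sum counts species photons:
    # w_i . (a_j p_j) = delta_ij a_j
    w_kept = amps[:, None] * w_kept
    weights = np.zeros((n_sp, n_flat))
    weights[:, retained] = w_kept
    n_chan = n_flat // n_detectors
    return FilterSet(weights=weights, patterns=patterns, total=total,
                     amplitudes=amps, n_detectors=n_detectors,
                     n_channels=n_chan)


def _most_collinear_pair(p: np.ndarray) -> tuple[int, int]:
    n = len(p)
    best, pair = -1.0, (0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            c = abs(np.dot(p[i], p[j])
                    / (np.linalg.norm(p[i]) * np.linalg.norm(p[j]) + 1e-300))
            if c > best:
                best, pair = c, (i, j)
    return pair


def expected_microtime_pattern(
    tau_ns: float, n_channels: int, rep_period_ns: float,
    irf_mean_ns: float = 2.0, irf_width_ns: float = 0.25,
    background_fraction: float = 0.0, tau2_ns: float | None = None,
) -> np.ndarray:
    """Analytic micro-time density: exponential decay (optionally convolved
    with a second exponential, for acceptor-delayed photons) under a
    Gaussian IRF, periodically wrapped, plus a uniform background floor."""
    width = rep_period_ns / n_channels
    t = (np.arange(n_channels) + 0.5) * width
    acc = np.zeros(n_channels)
    # wrap a few periods so the tail that spills past the period folds back
    for k in range(3):
        tt = t + k * rep_period_ns - irf_mean_ns
        if tau2_ns is None or abs(tau2_ns - tau_ns) < 1e-9:
            acc += _exp_gauss(tt, tau_ns, irf_width_ns)
        else:
            a = _exp_gauss(tt, tau_ns, irf_width_ns)
            b = _exp_gauss(tt, tau2_ns, irf_width_ns)
            acc += (tau_ns * a - tau2_ns * b) / (tau_ns - tau2_ns)
    acc = np.maximum(acc, 0.0)
    acc /= acc.sum()
    return (1 - background_fraction) * acc + background_fraction / n_channels


def species_pattern(
    efficiency: float, tau_da_ns: float, tau_acceptor_ns: float,
    n_channels: int, rep_period_ns: float,
    irf_mean_ns: float = 2.0, irf_width_ns: float = 0.25,
    background_fraction: float = 0.0,
) -> np.ndarray:
    """Expected flattened (4-detector, micro-channel) pattern of one FRET
    species: green detectors carry the quenched donor decay weighted by
    1 - E, red detectors the donor (x) acceptor cascade weighted by E;
    polarization split 50/50."""
    g = expected_microtime_pattern(tau_da_ns, n_channels, rep_period_ns,
                                   irf_mean_ns, irf_width_ns,
                                   background_fraction)
    r = expected_microtime_pattern(tau_da_ns, n_channels, rep_period_ns,
                                   irf_mean_ns, irf_width_ns,
                                   background_fraction,
                                   tau2_ns=tau_acceptor_ns)
    e = efficiency
    pat = np.concatenate([(1 - e) / 2 * g, (1 - e) / 2 * g,
                          e / 2 * r, e / 2 * r])
    return pat / pat.sum()


def measured_pattern(stream: PhotonStream, n_detectors: int = 4) -> np.ndarray:
    """Total measured (detector, micro-channel) histogram of a stream."""
    out = []
    for det in range(n_detectors):
        sel = stream.detectors == det
        out.append(np.bincount(stream.microtimes[sel],
                               minlength=stream.n_channels))
    return np.concatenate(out).astype(float)


def _exp_gauss(t, tau, sigma):
    """Exponential (x) Gaussian (EMG), normalized to unit area in t."""
    from scipy.special import erfc
    arg = (sigma / tau - t / sigma) / np.sqrt(2)
    return (0.5 / tau * np.exp(0.5 * (sigma / tau) ** 2 - t / tau)
            * erfc(arg))


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrCurve:
    kind: str                    # "sACF" | "sCCF" | "ACF"
    species: tuple
    lag_s: np.ndarray
    g: np.ndarray
    sd: np.ndarray | None = None
    bin_width_s: np.ndarray | None = None  # accumulator bin per lag
    params: dict = field(default_factory=dict)


def _multipletau(a: np.ndarray, b: np.ndarray, bin_s: float,
                 n_per_cascade: int = 16, min_lag_bins: int = 1):
    """Multiple-tau correlator on two binned weight traces.

    Returns (lags_s, G) with G = <a(t) b(t+tau)> / (<a><b>) - 1 using the
    symmetric (overlap-restricted) normalization.
    """
    lags, gs, widths = [], [], []
    level = 0
    width = bin_s
    aa, bb = a.astype(float), b.astype(float)
    while len(aa) >= 2 * n_per_cascade:
        start = min_lag_bins if level == 0 else n_per_cascade // 2
        for m in range(start, n_per_cascade):
            if m >= len(aa) - 8:
                break
            x, y = aa[:-m], bb[m:]
            n = len(x)
            mx, my = x.mean(), y.mean()
            if mx <= 0 or my <= 0:
                raise ValueError("total filtered intensity <= 0")
            gs.append(float(np.dot(x, y) / n / (mx * my) - 1.0))
            lags.append(m * width)
            widths.append(width)
        # coarsen by 2
        n2 = len(aa) // 2 * 2
        aa = aa[:n2].reshape(-1, 2).sum(axis=1)
        bb = bb[:n2].reshape(-1, 2).sum(axis=1)
        width *= 2
        level += 1
        if level > 30:
            break
    return np.asarray(lags), np.asarray(gs), np.asarray(widths)


def bin_stream_weights(stream: PhotonStream, weights: np.ndarray,
                       bin_s: float) -> np.ndarray:
    t = stream.times_s
    n_bins = int(np.ceil(stream.duration_s / bin_s)) + 1
    idx = np.minimum((t / bin_s).astype(np.int64), n_bins - 1)
    return np.bincount(idx, weights=weights, minlength=n_bins)


def correlate_filtered(
    stream: PhotonStream,
    filters: FilterSet | None,
    bin_s: float = 1e-6,
    n_per_cascade: int = 16,
    n_segments: int = 8,
    min_lag_s: float | None = None,
) -> list[CorrCurve]:
    """Species auto- and cross-correlations of a photon stream.

    With ``filters=None`` a single unfiltered ACF is returned.  Noise per
    lag is the standard deviation over ``n_segments`` equal stream segments
    (Wohland estimator), used as fit weights downstream.
    """
    if min_lag_s is None:
        min_lag_s = 4.0 * stream.sync_period_s
    min_lag_bins = max(int(np.ceil(min_lag_s / bin_s)), 1)

    if filters is None:
        traces = [np.ones(len(stream))]
        combos = [("ACF", (0, 0))]
    else:
        traces = [filters.photon_weights(stream, s)
                  for s in range(len(filters.weights))]
        ns = len(traces)
        combos = [("sACF", (i, i)) for i in range(ns)]
        combos += [("sCCF", (i, j)) for i in range(ns) for j in range(ns) if i != j]

    binned = [bin_stream_weights(stream, w, bin_s) for w in traces]
    curves = []
    for kind, (i, j) in combos:
        lag, g, widths = _multipletau(binned[i], binned[j], bin_s,
                                      n_per_cascade, min_lag_bins)
        # segment scatter for error bars
        seg_len = len(binned[i]) // n_segments
        seg_g = []
        for s in range(n_segments):
            sl = slice(s * seg_len, (s + 1) * seg_len)
            try:
                _, gg, _ = _multipletau(binned[i][sl], binned[j][sl], bin_s,
                                        n_per_cascade, min_lag_bins)
                seg_g.append(gg[: len(g)])
            except ValueError:
                continue
        if len(seg_g) >= 3:
            m = min(len(x) for x in seg_g)
            sd = np.std([x[:m] for x in seg_g], axis=0, ddof=1) \
                / np.sqrt(len(seg_g))
            sd = np.concatenate([sd, np.full(len(g) - m, sd[-1] if m else 1.0)])
        else:
            sd = None
        curves.append(CorrCurve(kind=kind, species=(i, j), lag_s=lag, g=g,
                                sd=sd, bin_width_s=widths))
    return curves


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _diffusion_kinetics(lag, n_mol, t_diff, s_ratio, amps, t_relax, offset,
                        bin_width=None):
    g = (1.0 / n_mol) / ((1.0 + lag / t_diff)
                         * np.sqrt(1.0 + lag / (s_ratio ** 2 * t_diff)))
    kin = 1.0
    for a, tr in zip(amps, t_relax):
        term = np.exp(-lag / tr)
        if bin_width is not None:
            # accumulator bins average the exponential over their width:
            # E[e^{-(t+u-v)/tR}] = e^{-t/tR} (sinh(x)/x)^2, x = w/(2 tR)
            x = np.asarray(bin_width) / (2.0 * tr)
            term = term * np.where(x > 1e-8, (np.sinh(x) / np.maximum(x, 1e-300)) ** 2, 1.0)
        kin = kin + a * term
    return g * kin + offset


def fit_correlations(
    curves: list[CorrCurve],
    n_relax: int = 0,
    global_relax: bool = True,
    s_ratio: float = 4.0,
    fit_s_ratio: bool = False,
    t_relax_guess: np.ndarray | None = None,
    overlap_warn_fraction: float = 0.1,
    max_lag_s: float | None = None,
) -> dict:
    """Weighted global fit of G(tc) = (1/N)(1+tc/td)^-1 (1+tc/(s^2 td))^-1/2
    x (1 + sum_i A_i exp(-tc/tRi)) + offset.

    Relaxation times are shared across curves when ``global_relax``;
    amplitudes (negative allowed, the sCCF anti-correlation) are per curve.
    Returns fitted parameters, per-parameter standard errors from the
    Jacobian, chi2r, and a flag when two relaxation times overlap within
    10% (not resolvable).  ``max_lag_s`` optionally bounds the fitted lag
    window; the far tail of a finite measurement carries normalization
    and re-entry artefacts the diffusion model does not cover.
    """
    if not curves:
        raise ValueError("need at least one curve")
    if max_lag_s is not None:
        trimmed = []
        for c in curves:
            keep = c.lag_s <= max_lag_s
            trimmed.append(CorrCurve(
                kind=c.kind, species=c.species, lag_s=c.lag_s[keep],
                g=c.g[keep],
                sd=c.sd[keep] if c.sd is not None else None,
                bin_width_s=(c.bin_width_s[keep]
                             if c.bin_width_s is not None else None),
                params=c.params))
        curves = trimmed
    n_c = len(curves)

    lag0 = curves[0].lag_s
    td0 = lag0[len(lag0) // 2]
    if t_relax_guess is None:
        t_relax_guess = np.geomspace(lag0[2], td0 / 2, n_relax) if n_relax else []
    amps0 = np.zeros((n_c, n_relax))
    for ic, c in enumerate(curves):
        amps0[ic, :] = -0.3 if c.kind == "sCCF" else 0.3

    # pack: per-curve log N, offset, amps; shared log t_diff, log t_relax
    def pack(n_mol, offs, amps, t_diff, t_rel, s_r):
        parts = [np.log(n_mol), offs, amps.ravel(), [np.log(t_diff)],
                 np.log(np.asarray(t_rel)) if n_relax else []]
        if fit_s_ratio:
            parts.append([np.log(s_r)])
        return np.concatenate([np.atleast_1d(np.asarray(p, float)) for p in parts])

    def unpack(theta):
        i = 0
        n_mol = np.exp(theta[i:i + n_c]); i += n_c
        offs = theta[i:i + n_c]; i += n_c
        amps = theta[i:i + n_c * n_relax].reshape(n_c, n_relax); i += n_c * n_relax
        t_diff = np.exp(theta[i]); i += 1
        t_rel = np.exp(theta[i:i + n_relax]); i += n_relax
        s_r = np.exp(theta[i]) if fit_s_ratio else s_ratio
        return n_mol, offs, amps, t_diff, t_rel, s_r

    n0 = np.array([max(1.0 / max(abs(c.g[0]), 1e-3), 0.1) for c in curves])
    theta0 = pack(n0, np.zeros(n_c), amps0, td0, t_relax_guess, s_ratio)

    def residuals(theta):
        n_mol, offs, amps, t_diff, t_rel, s_r = unpack(theta)
        res = []
        for ic, c in enumerate(curves):
            model = _diffusion_kinetics(c.lag_s, n_mol[ic], t_diff, s_r,
                                        amps[ic], t_rel, offs[ic],
                                        bin_width=c.bin_width_s)
            sd = c.sd if c.sd is not None else np.full(len(c.g), 1e-3)
            sd = np.maximum(sd, 1e-6)
            res.append((model - c.g) / sd)
        return np.concatenate(res)

    sol = optimize.least_squares(residuals, theta0, method="trf", x_scale="jac")
    n_mol, offs, amps, t_diff, t_rel, s_r = unpack(sol.x)
    order = np.argsort(t_rel) if n_relax else np.array([], dtype=int)
    t_rel = np.asarray(t_rel)[order]
    amps = amps[:, order] if n_relax else amps

    n_pts = sum(len(c.g) for c in curves)
    dof = max(n_pts - len(sol.x), 1)
    chi2r = float(2 * sol.cost / dof)
    # standard errors from the Jacobian
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj) * chi2r
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(sol.x), np.nan)

    flag = ""
    if n_relax >= 2:
        rel = np.diff(np.sort(t_rel)) / np.sort(t_rel)[:-1]
        if np.any(rel < overlap_warn_fraction):
            flag = "relaxation times overlap within 10%; n_relax not resolvable"

    i_td = 2 * n_c + n_c * n_relax
    se_trel = se[i_td + 1:i_td + 1 + n_relax] * t_rel if n_relax else np.array([])
    return {
        "n_molecules": n_mol, "offset": offs, "amplitudes": amps,
        "t_diff_s": float(t_diff), "t_diff_se_s": float(se[i_td] * t_diff),
        "t_relax_s": t_rel, "t_relax_se_s": se_trel,
        "s_ratio": float(s_r),
        "chi2": float(2 * sol.cost), "chi2r": chi2r,
        "n_points": n_pts, "n_free": len(sol.x),
        "success": bool(sol.success), "flag": flag,
    }


def curves_to_frame(curves: list[CorrCurve]):
    """Stacked (curve, lag_s, G, sd) table for CSV export."""
    import pandas as pd

    rows = []
    for c in curves:
        sd = c.sd if c.sd is not None else np.full(len(c.g), np.nan)
        for lag, g, s_ in zip(c.lag_s, c.g, sd):
            rows.append({"curve": f"{c.kind}{c.species}", "lag_s": lag,
                         "G": g, "sd": s_})
    return pd.DataFrame(rows)


def ftest_n_relax(fit_small: dict, fit_large: dict, alpha: float = 0.05) -> dict:
    """Does the larger relaxation spectrum significantly improve the fit?

    Standard nested-model F-test on the weighted chi2 of two fits of the
    same curves.  Returns the statistic, p-value, and the verdict at alpha.
    """
    chi2_1, p1 = fit_small["chi2"], fit_small["n_free"]
    chi2_2, p2 = fit_large["chi2"], fit_large["n_free"]
    n = fit_small["n_points"]
    dp = p2 - p1
    dof2 = max(n - p2, 1)
    if dp <= 0 or chi2_2 <= 0:
        raise ValueError("fits are not nested")
    f_stat = max((chi2_1 - chi2_2) / dp, 0.0) / (chi2_2 / dof2)
    p_value = float(stats.f.sf(f_stat, dp, dof2))
    return {"f": float(f_stat), "p": p_value, "demanded": p_value < alpha}
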
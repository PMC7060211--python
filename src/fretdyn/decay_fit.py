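"""Ensemble TCSPC decay analysis with Gaussian distance distributions.

Donor fluorescence quenched by FRET is modelled as a superposition of
conformers, each contributing a normal distribution of donor-acceptor
distances (the dye linkers broaden even a single conformation).  The
FRET-induced donor decay

    F(t) = x_D0 f_D(t) + (1 - x_D0) sum_i x_i Int p_i(R) f_D(t) e^{-t kFRET(R)} dR

with f_D(t) = sum_m a_m exp(-t/tau_Dm) and kFRET(R) = (R0/R)^6 / tau_D0
is reconvolved with the measured instrument response and fitted to the
photon histogram with Poisson weights.  Species fractions x_i can be shared
globally across many FRET variants while distances and widths stay local,
which is what resolves a weakly populated conformer from an ensemble of
datasets.  Uncertainties come from support-plane (profile chi-square)
scans with an F-test threshold, or from MCMC sampling of the Poisson
likelihood.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DecayCurve",
    "DecayDataset",
    "DistanceModel",
    "GlobalFitResult",
    "SupportPlaneResult",
    "fret_induced_donor_decay",
    "fit_decays_global",
    "support_plane_scan",
    "mcmc_uncertainty",
    "gaussian_irf",
]

N_QUAD = 441  # distance quadrature points over mean +/- 5 widths
R_MIN_A = 1.0  # truncation of the normal distance distribution (Angstrom)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DecayCurve:
    """A decay histogram on a uniform time grid (ns)."""

    t_ns: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.t_ns = np.asarray(self.t_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.t_ns.shape != self.counts.shape:
            raise ValueError("time grid and counts must have the same shape")
        if len(self.t_ns) > 1:
            dt = np.diff(self.t_ns)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time grid must be uniform")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def dt_ns(self) -> float:
        return float(self.t_ns[1] - self.t_ns[0])

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t_ns, self.counts]),
                   header="time_ns counts")

    @classmethod
    def from_text(cls, path) -> "DecayCurve":
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1])


@dataclass
class DecayDataset:
    """A FRET (DA) decay with its donor-only reference and IRF."""

    da: DecayCurve
    irf: DecayCurve
    donly: DecayCurve | None = None
    scatter_fraction: float = 0.0
    background: float = 0.0          # counts per channel
    shift_channels: float = 0.0      # IRF -> data time shift
    fit_range: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.da.t_ns)
        if len(self.irf.t_ns) != n:
            raise ValueError("DA and IRF curves must share the channel grid")
        if self.donly is not None and len(self.donly.t_ns) != n:
            raise ValueError("DOnly curve must share the channel grid")
        if np.sum(self.irf.counts) <= 0:
            raise ValueError("IRF has zero mass")
        if self.fit_range is None:
            self.fit_range = (0, n)
        lo, hi = self.fit_range
        if not (0 <= lo < hi <= n):
            raise ValueError("fit range outside channel grid")


@dataclass
class DistanceModel:
    """Mixture of normal-distributed DA distances plus a donor-only term."""

    fractions: np.ndarray          # conformer species fractions, sum to 1
    distances_A: np.ndarray        # mean DA distances (Angstrom)
    widths_A: np.ndarray           # distribution widths (Angstrom)
    x_donly: float = 0.0
    donor_amplitudes: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    donor_taus_ns: np.ndarray = field(default_factory=lambda: np.array([4.0]))
    r0_A: float = 52.0
    kappa2_isotropic: bool = True  # kappa^2 = 2/3 orientation assumption

    def __post_init__(self) -> None:
        self.fractions = np.atleast_1d(np.asarray(self.fractions, dtype=float))
        self.distances_A = np.atleast_1d(np.asarray(self.distances_A, dtype=float))
        self.widths_A = np.atleast_1d(np.asarray(self.widths_A, dtype=float))
        self.donor_amplitudes = np.atleast_1d(np.asarray(self.donor_amplitudes, float))
        self.donor_taus_ns = np.atleast_1d(np.asarray(self.donor_taus_ns, float))
        if self.r0_A <= 0:
            raise ValueError("Forster radius must be positive")
        if self.donor_amplitudes.size == 0:
            raise ValueError("donor lifetime spectrum is empty")
        if not np.isclose(self.fractions.sum(), 1.0, atol=1e-6):
            raise ValueError("conformer fractions must sum to 1")
        if not (0.0 <= self.x_donly <= 1.0):
            raise ValueError("x_donly must be in [0, 1]")
        if np.any(self.distances_A <= 0) or np.any(self.widths_A <= 0):
            raise ValueError("distances and widths must be positive")
        if not np.isclose(self.donor_amplitudes.sum(), 1.0, atol=1e-6):
            raise ValueError("donor amplitudes must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.fractions)

    @property
    def tau_d0_ns(self) -> float:
        """Species-averaged donor-only lifetime sum(a_m tau_m)."""
        return float(np.sum(self.donor_amplitudes * self.donor_taus_ns))


@dataclass
class GlobalFitResult:
    distances_A: np.ndarray        # (n_datasets, n_components)
    widths_A: np.ndarray
    fractions: np.ndarray          # shared (n_components,)
    x_donly: np.ndarray            # per dataset
    scatter: np.ndarray
    chi2r: np.ndarray              # per dataset
    chi2r_global: float
    n_free: int
    n_channels: int
    success: bool
    models: list = field(default_factory=list)
    message: str = ""
    theta: np.ndarray | None = None
    samples: np.ndarray | None = None  # optional MCMC samples


@dataclass
class SupportPlaneResult:
    values: np.ndarray
    chi2r: np.ndarray
    threshold: float
    ci: tuple[float, float]
    best_value: float
    grid_covers_optimum: bool
    dr_minus: float | None = None
    dr_plus: float | None = None


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def fret_induced_donor_decay(model: DistanceModel, t_ns: np.ndarray) -> np.ndarray:
    """Donor decay quenched by the distance-distributed FRET rate.

    Evaluated on a fixed 441-point quadrature grid spanning each component's
    mean +/- 5 widths, truncated at R >= 1 A and renormalized.  Returns the
    unnormalized model F(t) with F(0) = 1.
    """
    t = np.asarray(t_ns, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    f_d = _donor_decay(model, t)
    tau_d0 = model.tau_d0_ns
    out = model.x_donly * f_d
    mix = np.zeros_like(t)
    uniform = len(t) > 2 and np.allclose(np.diff(t), t[1] - t[0], rtol=1e-9)
    for x_i, mu, w in zip(model.fractions, model.distances_A, model.widths_A):
        r = np.linspace(max(R_MIN_A, mu - 5.0 * w), mu + 5.0 * w, N_QUAD)
        p = np.exp(-0.5 * ((r - mu) / w) ** 2)
        p /= p.sum()
        k = (model.r0_A / r) ** 6 / tau_d0          # FRET rate (1/ns)
        quench = p @ _exp_decay_grid(k, t, uniform)
        mix += x_i * quench
    out = out + (1.0 - model.x_donly) * f_d * mix
    return out


def _exp_decay_grid(k: np.ndarray, t: np.ndarray, uniform: bool) -> np.ndarray:
    """exp(-k t) on a grid; on uniform grids a cumulative product replaces
    most of the exp calls (exp(-k t_i) = exp(-k t_0) ratio^i)."""
    if not uniform:
        return np.exp(-np.outer(k, t))
    dt = t[1] - t[0]
    ratio = np.exp(-k * dt)
    m = np.empty((len(k), len(t)))
    m[:, 0] = np.exp(-k * t[0])
    m[:, 1:] = ratio[:, None]
    return np.cumprod(m, axis=1)


def _donor_decay(model: DistanceModel, t: np.ndarray) -> np.ndarray:
    a = model.donor_amplitudes
    tau = model.donor_taus_ns
    return np.exp(-np.outer(1.0 / tau, t)).T @ a


def gaussian_irf(t_ns: np.ndarray, mean_ns: float = 2.0,
                 width_ns: float = 0.25, total: float = 1.0) -> DecayCurve:
    """Synthetic Gaussian instrument response on a channel grid."""
    t = np.asarray(t_ns, dtype=float)
    c = np.exp(-0.5 * ((t - mean_ns) / max(width_ns, 1e-6)) ** 2)
    c = c / c.sum() * total
    return DecayCurve(t, c)


def _shift_curve(y: np.ndarray, shift_channels: float) -> np.ndarray:
    if shift_channels == 0.0:
        return y
    n = len(y)
    idx = np.arange(n) - shift_channels
    return np.interp(idx, np.arange(n), y, left=0.0, right=0.0)


def model_curve(dataset: DecayDataset, model: DistanceModel,
                amplitude: float | None = None) -> np.ndarray:
    """Reconvolved model for one dataset: IRF (x) F + scatter*IRF + bg.

    With ``amplitude=None`` the amplitude is solved analytically by
    Poisson-weighted projection onto the data, the standard trick that keeps
    the nonlinear parameter count down.
    """
    irf = _shift_curve(dataset.irf.counts, dataset.shift_channels)
    irf_n = irf / irf.sum()
    f = fret_induced_donor_decay(model, dataset.da.t_ns - dataset.da.t_ns[0])
    conv = np.convolve(irf_n, f)[: len(f)]
    sc = dataset.scatter_fraction
    shape = (1.0 - sc) * conv / conv.sum() + sc * irf_n
    if amplitude is None:
        lo, hi = dataset.fit_range
        data = dataset.da.counts
        var = np.maximum(data, 1.0)
        s, d, v = shape[lo:hi], data[lo:hi], var[lo:hi]
        denom = np.sum(s * s / v)
        amplitude = max(np.sum((d - dataset.background) * s / v) / denom, 0.0) \
            if denom > 0 else 0.0
    return amplitude * shape + dataset.background


def _weighted_residuals(dataset: DecayDataset, model: DistanceModel) -> np.ndarray:
    lo, hi = dataset.fit_range
    m = model_curve(dataset, model)
    d = dataset.da.counts
    sigma = np.sqrt(np.maximum(d, 1.0))
    return ((m - d) / sigma)[lo:hi]


# ---------------------------------------------------------------------------
# parameter packing for the global fit
# ---------------------------------------------------------------------------

class _Packer:
    """Maps between a flat optimizer vector and per-dataset distance models.

    Fractions are shared across datasets (softmax over logits, last logit
    pinned to zero); distances/widths are per dataset in log space; the
    donor-only fraction is per dataset through a logit.  Any parameter can
    be clamped through ``fixed`` for support-plane scans.
    """

    def __init__(self, n_comp: int, n_ds: int, base: list[DistanceModel],
                 fit_donly: bool = True, fixed: dict | None = None):
        self.n_comp = n_comp
        self.n_ds = n_ds
        self.base = base
        self.fit_donly = fit_donly
        self.fixed = dict(fixed or {})
        self.fixed_frac = {k[1]: v for k, v in self.fixed.items()
                           if k[0] == "fraction"}
        free_frac = [i for i in range(n_comp) if i not in self.fixed_frac]
        # softmax over the free fractions, last one pinned
        self.frac_logit_idx = free_frac[:-1]
        self.frac_free = free_frac
        self.names: list[tuple] = [("logit_frac", i) for i in self.frac_logit_idx]
        for d in range(n_ds):
            for i in range(n_comp):
                if ("distance", d, i) not in self.fixed:
                    self.names.append(("log_r", d, i))
                if ("width", d, i) not in self.fixed:
                    self.names.append(("log_w", d, i))
            if fit_donly and ("x_donly", d) not in self.fixed:
                self.names.append(("logit_xd0", d))
        self.size = len(self.names)

    def pack(self, models: list[DistanceModel]) -> np.ndarray:
        theta = np.empty(self.size)
        x = models[0].fractions
        budget = 1.0 - sum(self.fixed_frac.values())
        ref = self.frac_free[-1]
        for j, name in enumerate(self.names):
            kind = name[0]
            if kind == "logit_frac":
                i = name[1]
                theta[j] = np.log(max(x[i], 1e-8) / max(x[ref], 1e-8))
            elif kind == "log_r":
                theta[j] = np.log(models[name[1]].distances_A[name[2]])
            elif kind == "log_w":
                theta[j] = np.log(models[name[1]].widths_A[name[2]])
            elif kind == "logit_xd0":
                xd = np.clip(models[name[1]].x_donly, 1e-6, 1 - 1e-6)
                theta[j] = np.log(xd / (1 - xd))
        del budget
        return theta

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(self.size)
        hi = np.empty(self.size)
        for j, name in enumerate(self.names):
            if name[0] == "log_r":
                lo[j], hi[j] = np.log(5.0), np.log(150.0)
            elif name[0] == "log_w":
                lo[j], hi[j] = np.log(0.3), np.log(60.0)
            else:
                lo[j], hi[j] = -12.0, 12.0
        return lo, hi

    def unpack(self, theta: np.ndarray) -> list[DistanceModel]:
        theta = np.clip(np.nan_to_num(theta, nan=0.0), -30.0, 30.0)
        budget = 1.0 - sum(self.fixed_frac.values())
        z = np.zeros(len(self.frac_free))
        for j, name in enumerate(self.names):
            if name[0] == "logit_frac":
                z[self.frac_free.index(name[1])] = theta[j]
        ez = np.exp(z - z.max())
        soft = ez / ez.sum() * budget
        fractions = np.empty(self.n_comp)
        for pos, i in enumerate(self.frac_free):
            fractions[i] = soft[pos]
        for i, v in self.fixed_frac.items():
            fractions[i] = v
        models = []
        for d in range(self.n_ds):
            m = self.base[d]
            r = m.distances_A.copy()
            w = m.widths_A.copy()
            xd0 = m.x_donly
            for j, name in enumerate(self.names):
                if name[0] == "log_r" and name[1] == d:
                    r[name[2]] = np.exp(theta[j])
                elif name[0] == "log_w" and name[1] == d:
                    w[name[2]] = np.exp(theta[j])
                elif name[0] == "logit_xd0" and name[1] == d:
                    xd0 = 1.0 / (1.0 + np.exp(-theta[j]))
            for key, v in self.fixed.items():
                if key[0] == "distance" and key[1] == d:
                    r[key[2]] = v
                elif key[0] == "width" and key[1] == d:
                    w[key[2]] = v
                elif key[0] == "x_donly" and key[1] == d:
                    xd0 = v
            models.append(replace(m, fractions=fractions, distances_A=r,
                                  widths_A=w, x_donly=xd0))
        return models


def _global_residuals(theta, packer: _Packer, datasets) -> np.ndarray:
    models = packer.unpack(theta)
    return np.concatenate([_weighted_residuals(ds, m)
                           for ds, m in zip(datasets, models)])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _default_start(datasets, n_components, donor_amplitudes, donor_taus_ns,
                   r0_A) -> list[DistanceModel]:
    # spread starting distances around R0 where the decay is most sensitive
    lo, hi = 0.65, 1.25
    r_start = r0_A * np.linspace(lo, hi, n_components)
    return [DistanceModel(
        fractions=np.full(n_components, 1.0 / n_components),
        distances_A=r_start.copy(),
        widths_A=np.full(n_components, 6.0),
        x_donly=0.05,
        donor_amplitudes=donor_amplitudes,
        donor_taus_ns=donor_taus_ns,
        r0_A=r0_A,
    ) for _ in datasets]


def _lhs_starts(rng: np.random.Generator, n_restarts, n_components,
                r0_A) -> list[np.ndarray]:
    """Latin-hypercube component-distance starts over [0.6, 1.3] R0."""
    starts = []
    for _ in range(n_restarts):
        u = (rng.permutation(n_components) + rng.random(n_components)) / n_components
        starts.append(np.sort(r0_A * (0.6 + 0.7 * u)))
    return starts


def fit_decays_global(
    datasets: list[DecayDataset],
    n_components: int,
    start: list[DistanceModel] | None = None,
    donor_amplitudes=None,
    donor_taus_ns=None,
    r0_A: float = 52.0,
    fit_donly: bool = True,
    share_donly: bool = False,
    n_restarts: int = 8,
    seed: int = 0,
    fixed: dict | None = None,
    max_nfev: int | None = None,
) -> GlobalFitResult:
    """Jointly fit one or more TCSPC datasets with shared species fractions.

    When ``start`` is given it is used as the single warm start; otherwise
    ``n_restarts`` latin-hypercube seeds over the distance space are tried
    and the best kept (the 3-component surface is multi-modal).  The donor
    lifetime spectrum is taken from the DOnly reference of each dataset when
    not supplied explicitly (a single-exponential MLE on the tail).
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if not datasets:
        raise ValueError("need at least one dataset")
    if donor_amplitudes is None or donor_taus_ns is None:
        donor_amplitudes, donor_taus_ns = _donly_spectrum(datasets[0])
    donor_amplitudes = np.atleast_1d(np.asarray(donor_amplitudes, float))
    donor_taus_ns = np.atleast_1d(np.asarray(donor_taus_ns, float))

    warm = start is not None
    if start is None:
        start = _default_start(datasets, n_components, donor_amplitudes,
                               donor_taus_ns, r0_A)
    packer = _Packer(n_components, len(datasets), start,
                     fit_donly=fit_donly, fixed=fixed)

    rng = np.random.default_rng(seed)
    theta_starts = [packer.pack(start)]
    if not warm and n_components > 1 and n_restarts > 1:
        for r_start in _lhs_starts(rng, n_restarts - 1, n_components, r0_A):
            trial = [replace(m, distances_A=r_start.copy()) for m in start]
            theta_starts.append(packer.pack(trial))

    lo, hi = packer.bounds()

    def _minimize(pk, th0, nfev):
        l, h = pk.bounds()
        return optimize.least_squares(
            _global_residuals, np.clip(th0, l + 1e-9, h - 1e-9),
            args=(pk, datasets), method="trf", x_scale="jac", bounds=(l, h),
            ftol=1e-7, xtol=1e-7, max_nfev=nfev,
        )

    best = None
    for theta0 in theta_starts:
        if warm:
            sol = _minimize(packer, theta0, max_nfev)
        else:
            # stage 1: widths clamped -- the collapsed-width local minima
            # of the full problem are avoided by fitting the distance/
            # fraction skeleton first
            stage_fixed = dict(fixed or {})
            trial = packer.unpack(theta0)
            for d in range(len(datasets)):
                for i in range(n_components):
                    stage_fixed.setdefault(("width", d, i),
                                           float(trial[d].widths_A[i]))
            pk1 = _Packer(n_components, len(datasets), trial,
                          fit_donly=fit_donly, fixed=stage_fixed)
            s1 = _minimize(pk1, pk1.pack(trial), max_nfev)
            # stage 2: release widths from the stage-1 skeleton
            sol = _minimize(packer, packer.pack(pk1.unpack(s1.x)), max_nfev)
        if best is None or sol.cost < best.cost:
            best = sol

    models = packer.unpack(best.x)
    models = _sort_components(models, packer.fixed)
    theta = packer.pack(models)

    chi2r = []
    n_ch = 0
    for ds, m in zip(datasets, models):
        r = _weighted_residuals(ds, m)
        lo, hi = ds.fit_range
        n_d = hi - lo
        n_ch += n_d
        # per-dataset chi2r against its own share of free parameters
        p_d = max(packer.size / len(datasets), 1.0)
        chi2r.append(float(np.sum(r ** 2) / max(n_d - p_d, 1)))
    n_free = packer.size
    chi2_global = float(2 * best.cost / max(n_ch - n_free, 1))

    return GlobalFitResult(
        distances_A=np.array([m.distances_A for m in models]),
        widths_A=np.array([m.widths_A for m in models]),
        fractions=models[0].fractions.copy(),
        x_donly=np.array([m.x_donly for m in models]),
        scatter=np.array([ds.scatter_fraction for ds in datasets]),
        chi2r=np.array(chi2r),
        chi2r_global=chi2_global,
        n_free=n_free,
        n_channels=n_ch,
        success=bool(best.success),
        models=models,
        message=best.message if not best.success else "",
        theta=theta,
    )


def _sort_components(models: list[DistanceModel], fixed: dict) -> list[DistanceModel]:
    """Break label switching: sort components by mean distance (averaged
    over datasets).  Skipped when any component parameter is clamped, so a
    support-plane scan keeps its target index."""
    if any(k[0] in ("distance", "width", "fraction") for k in fixed):
        return models
    mean_r = np.mean([m.distances_A for m in models], axis=0)
    order = np.argsort(mean_r)
    return [replace(m, fractions=m.fractions[order],
                    distances_A=m.distances_A[order],
                    widths_A=m.widths_A[order]) for m in models]


def _donly_spectrum(dataset: DecayDataset) -> tuple[np.ndarray, np.ndarray]:
    """Single-exponential donor lifetime from the DOnly tail (moment fit)."""
    if dataset.donly is None:
        raise ValueError("dataset has no DOnly curve and no spectrum was given")
    c = dataset.donly.counts
    t = dataset.donly.t_ns
    peak = int(np.argmax(c))
    lo = min(peak + 5, len(c) - 10)
    w = c[lo:]
    tt = t[lo:] - t[lo]
    if np.sum(w) <= 0:
        return np.array([1.0]), np.array([4.0])
    tbar = float(np.sum(w * tt) / np.sum(w))
    T = float(tt[-1])
    # window-truncated exponential: <t> = tau - T/(e^{T/tau} - 1)
    tau = tbar
    for _ in range(100):
        tau_new = tbar + T / np.expm1(T / tau)
        if abs(tau_new - tau) < 1e-10:
            tau = tau_new
            break
        tau = tau_new
    return np.array([1.0]), np.array([max(tau, 0.1)])


# ---------------------------------------------------------------------------
# uncertainty: support planes and MCMC
# ---------------------------------------------------------------------------

def ftest_threshold(chi2r_min: float, n_free: int, n_channels: int,
                    confidence: float = 0.68) -> float:
    """chi2r acceptance threshold: chi2_min [1 + p/(n-p) F_{1-a}(p, n-p)]."""
    p, n = n_free, n_channels
    f = stats.f.ppf(confidence, p, max(n - p, 1))
    return chi2r_min * (1.0 + p / max(n - p, 1) * f)


def support_plane_scan(
    datasets: list[DecayDataset],
    result: GlobalFitResult,
    parameter: tuple,
    grid: np.ndarray,
    confidence: float = 0.68,
    max_nfev: int = 200,
) -> SupportPlaneResult:
    """Profile the global chi2r along one parameter.

    ``parameter`` is ("fraction", i), ("distance", d, i) or ("width", d, i).
    At each grid value the parameter is clamped and every other parameter is
    re-optimized, warm-starting from the neighbouring grid point.  The
    confidence interval collects grid values whose chi2r stays below the
    F-test threshold; for distance parameters the same threshold yields the
    asymmetric statistical errors (shortest and longest distance below the
    1-sigma threshold).
    """
    grid = np.asarray(grid, dtype=float)
    models = result.models
    chi2_curve = np.empty(len(grid))
    best_val = _param_value(result, parameter)

    current = models
    results_up = {}
    order = np.argsort(np.abs(grid - best_val))  # walk outward from optimum
    for idx in order:
        fixed = {parameter: float(grid[idx])}
        sub = fit_decays_global(
            datasets, result.fractions.size, start=_clamped_start(current, parameter, grid[idx]),
            donor_amplitudes=models[0].donor_amplitudes,
            donor_taus_ns=models[0].donor_taus_ns,
            r0_A=models[0].r0_A, fixed=fixed, n_restarts=1,
            max_nfev=max_nfev,
        )
        results_up[idx] = sub
        chi2_curve[idx] = sub.chi2r_global
        current = sub.models

    thresh = ftest_threshold(result.chi2r_global, result.n_free,
                             result.n_channels, confidence)
    # the continuous optimum is below threshold by construction, so the
    # interval always contains it even on a coarse grid
    below = grid[chi2_curve <= thresh]
    ci = (float(min(below.min(), best_val)) if below.size else best_val,
          float(max(below.max(), best_val)) if below.size else best_val)
    covers = bool(grid.min() <= best_val <= grid.max())
    if not covers:
        warnings.warn("support-plane grid does not cover the fit optimum")
    dr_minus = dr_plus = None
    if parameter[0] == "distance":
        dr_minus = max(best_val - ci[0], 0.0)
        dr_plus = max(ci[1] - best_val, 0.0)
    return SupportPlaneResult(
        values=grid, chi2r=chi2_curve, threshold=thresh, ci=ci,
        best_value=best_val, grid_covers_optimum=covers,
        dr_minus=dr_minus, dr_plus=dr_plus,
    )


def profile_at(
    datasets: list[DecayDataset],
    result: GlobalFitResult,
    parameter: tuple,
    value: float,
    steps: int = 2,
    max_nfev: int = 120,
) -> float:
    """Profile chi2r at one parameter value, walking there from the fit
    optimum in warm-started steps.  A value belongs to the support-plane
    confidence region iff the returned chi2r stays below the F-test
    threshold of the baseline fit."""
    models = result.models
    best_val = _param_value(result, parameter)
    current = models
    chi2 = result.chi2r_global
    for v in np.linspace(best_val, value, steps + 1)[1:]:
        sub = fit_decays_global(
            datasets, result.fractions.size,
            start=_clamped_start(current, parameter, v),
            donor_amplitudes=models[0].donor_amplitudes,
            donor_taus_ns=models[0].donor_taus_ns,
            r0_A=models[0].r0_A, fixed={parameter: float(v)},
            n_restarts=1, max_nfev=max_nfev,
        )
        current = sub.models
        chi2 = sub.chi2r_global
    return chi2


def _param_value(result: GlobalFitResult, parameter: tuple) -> float:
    if parameter[0] == "fraction":
        return float(result.fractions[parameter[1]])
    if parameter[0] == "distance":
        return float(result.distances_A[parameter[1], parameter[2]])
    if parameter[0] == "width":
        return float(result.widths_A[parameter[1], parameter[2]])
    raise ValueError(f"unknown parameter {parameter}")


def _clamped_start(models, parameter, value):
    out = []
    for d, m in enumerate(models):
        if parameter[0] == "distance" and parameter[1] == d:
            r = m.distances_A.copy()
            r[parameter[2]] = value
            m = replace(m, distances_A=r)
        elif parameter[0] == "width" and parameter[1] == d:
            w = m.widths_A.copy()
            w[parameter[2]] = value
            m = replace(m, widths_A=w)
        out.append(m)
    if parameter[0] == "fraction":
        i = parameter[1]
        new = []
        for m in out:
            x = m.fractions.copy()
            others = np.delete(np.arange(len(x)), i)
            rest = x[others].sum()
            if rest > 0:
                x[others] *= (1.0 - value) / rest
            x[i] = value
            new.append(replace(m, fractions=x))
        out = new
    return out


def mcmc_uncertainty(
    dataset: DecayDataset,
    model: DistanceModel,
    n_samples: int = 500,
    seed: int = 0,
    n_walkers: int | None = None,
    burn_fraction: float = 0.3,
):
    """Sample the Poisson likelihood of a single decay around a converged fit.

    Returns ``(samples, acceptance_fraction, flag)`` where samples has one
    column per free parameter (distances, widths, fractions via logits,
    donor-only fraction) mapped back to natural units.  ``flag`` is set when
    the mean acceptance rate leaves [0.05, 0.9].
    """
    import emcee

    packer = _Packer(model.n_components, 1, [model], fit_donly=True)
    theta0 = packer.pack([model])
    ndim = packer.size
    if n_walkers is None:
        n_walkers = max(2 * ndim + 2, 8)

    lo, hi = dataset.fit_range
    data = dataset.da.counts[lo:hi]

    def log_prob(theta):
        if np.any(np.abs(theta) > 20):
            return -np.inf
        try:
            m = packer.unpack(theta)[0]
            mu = model_curve(dataset, m)[lo:hi]
        except (ValueError, FloatingPointError):
            return -np.inf
        mu = np.maximum(mu, 1e-12)
        return float(np.sum(data * np.log(mu) - mu))

    rng = np.random.default_rng(seed)
    p0 = theta0 + 1e-3 * rng.standard_normal((n_walkers, ndim))
    sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
    state = rng.integers(0, 2**31)
    sampler.random_state = np.random.RandomState(state).get_state()
    sampler.run_mcmc(p0, n_samples, progress=False)
    burn = int(burn_fraction * n_samples)
    chain = sampler.get_chain(discard=burn, flat=True)
    acc = float(np.mean(sampler.acceptance_fraction))
    flagged = not (0.05 <= acc <= 0.9)

    # map back to natural units
    nat = np.empty_like(chain)
    cols = []
    for j, name in enumerate(packer.names):
        cols.append(name)
    for row in range(chain.shape[0]):
        ms = packer.unpack(chain[row])[0]
        for j, name in enumerate(cols):
            if name[0] == "logit_frac":
                nat[row, j] = ms.fractions[name[1]]
            elif name[0] == "log_r":
                nat[row, j] = ms.distances_A[name[2]]
            elif name[0] == "log_w":
                nat[row, j] = ms.widths_A[name[2]]
            elif name[0] == "logit_xd0":
                nat[row, j] = ms.x_donly
    return nat, acc, flagged


def fit_report_frame(result: GlobalFitResult):
    """Long-format fit report (one row per dataset and component), ready
    for CSV export."""
    import pandas as pd

    rows = []
    n_ds, n_comp = result.distances_A.shape
    for d in range(n_ds):
        for i in range(n_comp):
            rows.append({
                "dataset": d, "component": i,
                "fraction": result.fractions[i],
                "distance_A": result.distances_A[d, i],
                "width_A": result.widths_A[d, i],
                "x_donly": result.x_donly[d],
                "chi2r_dataset": result.chi2r[d],
                "chi2r_global": result.chi2r_global,
            })
    return pd.DataFrame(rows)


def fit_report_json(result: GlobalFitResult) -> str:
    return json.dumps({
        "fractions": result.fractions.tolist(),
        "distances_A": result.distances_A.tolist(),
        "widths_A": result.widths_A.tolist(),
        "x_donly": result.x_donly.tolist(),
        "chi2r": result.chi2r.tolist(),
        "chi2r_global": result.chi2r_global,
        "n_free": result.n_free,
        "success": result.success,
    }, indent=2)
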
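"""Three-state linear kinetic networks for conformational exchange.

A linear chain C1 <-> C2 <-> C3 with rate constants k12, k21, k23, k32
(ms^-1) has a rate matrix K whose nonzero eigenvalues set the relaxation
times observed in filtered FCS, and whose null space gives the equilibrium
species fractions observed in ensemble decay fits.  The inverse problem --
recovering the four rate constants from two relaxation times and three
fractions -- has up to two physical solutions, which differ in whether the
C1-C2 or the C2-C3 exchange carries the fast relaxation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateNetwork",
    "EnergyLandscape",
    "relaxation_spectrum",
    "invert_three_state",
    "energy_landscape",
]

#: Boltzmann constant in kJ/(mol K); energies are reported in kBT units so
#: the numerical value only matters if a caller converts to absolute units.
KB_KJ_PER_MOL_K = 0.0083144626


class UnsupportedTopologyError(ValueError):
    """Raised when an operation is asked for a network topology it does not
    support (e.g. inversion of a cyclic three-state scheme)."""


@dataclass
class RateNetwork:
    """Linear three-state chain C1 <-> C2 <-> C3.

    Rates are in ms^-1.  ``k13``/``k31`` are carried so that a cyclic
    topology is *representable*, but inversion refuses it.
    """

    k12: float
    k21: float
    k23: float
    k32: float
    k13: float = 0.0
    k31: float = 0.0
    labels: tuple[str, str, str] = ("C1", "C2", "C3")

    def __post_init__(self) -> None:
        for name in ("k12", "k21", "k23", "k32", "k13", "k31"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")

    @property
    def is_cyclic(self) -> bool:
        return self.k13 > 0 or self.k31 > 0

    def rate_matrix(self) -> np.ndarray:
        """Rate matrix K (ms^-1) with columns summing to zero; dp/dt = K p."""
        k12, k21, k23, k32 = self.k12, self.k21, self.k23, self.k32
        k13, k31 = self.k13, self.k31
        return np.array(
            [
                [-(k12 + k13), k21, k31],
                [k12, -(k21 + k23), k32],
                [k13, k23, -(k32 + k31)],
            ]
        )

    def equilibrium_fractions(self) -> np.ndarray:
        """Stationary distribution from the null space of K."""
        K = self.rate_matrix()
        w, v = np.linalg.eig(K)
        i = int(np.argmin(np.abs(w)))
        x = np.real(v[:, i])
        x = np.abs(x)
        return x / x.sum()

    def chain_equilibrium(self) -> np.ndarray:
        """Detailed-balance stationary vector of the linear chain; robust
        to zero rate pairs (a detached tail state gets zero weight)."""
        if self.is_cyclic:
            return self.equilibrium_fractions()
        w = np.zeros(3)
        w[0] = 1.0
        if self.k21 > 0:
            w[1] = w[0] * self.k12 / self.k21
        elif self.k12 > 0:      # forward-absorbing into C2/C3
            w[0], w[1] = 0.0, 1.0
        if self.k32 > 0:
            w[2] = w[1] * self.k23 / self.k32
        elif self.k23 > 0 and w[1] > 0:
            w[:2] = 0.0
            w[2] = 1.0
        s = w.sum()
        return w / s if s > 0 else np.array([1.0, 0.0, 0.0])

    def relaxation_times_ms(self) -> np.ndarray:
        return relaxation_spectrum(self)[0]

    # -- simple JSON round trip used by the CLI -------------------------
    def to_json(self, temperature_K: float = 298.0) -> str:
        return json.dumps(
            {
                "states": list(self.labels),
                "rates_ms^-1": {
                    "k12": self.k12,
                    "k21": self.k21,
                    "k23": self.k23,
                    "k32": self.k32,
                    "k13": self.k13,
                    "k31": self.k31,
                },
                "temperature_K": temperature_K,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RateNetwork":
        obj = json.loads(text)
        r = obj["rates_ms^-1"]
        return cls(
            k12=r["k12"], k21=r["k21"], k23=r["k23"], k32=r["k32"],
            k13=r.get("k13", 0.0), k31=r.get("k31", 0.0),
            labels=tuple(obj.get("states", ("C1", "C2", "C3"))),
        )


@dataclass
class EnergyLandscape:
    """Relative Gibbs free energies (kBT units) over a rate network.

    ``delta_g0[(i, j)]`` is the free-energy difference of state j relative
    to state i; ``delta_g_act[(i, j)]`` the activation barrier of the
    directed step i->j relative to the Arrhenius prefactor ``k0``.
    """

    delta_g0: dict = field(default_factory=dict)
    delta_g_act: dict = field(default_factory=dict)
    k0_per_ms: float = 1e3
    temperature_K: float = 298.0

    def to_frame(self):
        """Per-transition table (kBT units) for CSV export."""
        import pandas as pd

        rows = [{"from": i, "to": j, "dG0_kBT": v,
                 "dG_act_kBT": self.delta_g_act.get((i, j))}
                for (i, j), v in self.delta_g0.items()]
        return pd.DataFrame(rows)


def relaxation_spectrum(network: RateNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Relaxation times (ms, ascending) and equilibrium fractions.

    The nonzero eigenvalues lambda of the rate matrix give t_R = -1/lambda;
    for a two-state collapse (one rate pair zero) only one finite t_R is
    returned.  A disconnected network (zero eigenvalue with multiplicity
    above one) is rejected.
    """
    K = network.rate_matrix()
    w = np.linalg.eigvals(K)
    w = np.real_if_close(w, tol=1e6)
    scale = max(np.max(np.abs(w)), 1.0)
    zero = np.abs(w) < 1e-12 * scale
    if zero.sum() > 1:
        raise ValueError("disconnected network: zero eigenvalue multiplicity > 1")
    lam = np.sort(np.real(w[~zero]))  # most negative first
    t_r = np.sort(-1.0 / lam)  # ascending relaxation times
    return t_r, network.equilibrium_fractions()


def invert_three_state(
    t_r1: float, t_r2: float, x1: float, x2: float, x3: float,
    merge_tol: float = 1e-6, topology: str = "linear",
) -> list[RateNetwork]:
    """Invert (relaxation times, equilibrium fractions) to rate constants.

    For the linear chain, with a = x2/x1 and b = x3/x2 (detailed balance
    k12 = a*k21, k23 = b*k32), the eigenvalue sum and product constraints

        S = k21*(1 + a) + k32*(1 + b) = 1/t_R1 + 1/t_R2
        P = k21*k32*(1 + a + a*b)     = 1/(t_R1*t_R2)

    reduce to a quadratic in u = k21*(1 + a); its two roots are the two
    competing kinetic solutions, which exchange which state pair carries the
    fast relaxation.  Solutions are returned fast-C1C2 first; double roots
    within ``merge_tol`` relative are merged.

    Parameters are in ms; rates come back in ms^-1.
    """
    if topology != "linear":
        raise UnsupportedTopologyError(
            f"inversion supports only the linear chain, not {topology!r}; "
            "a cyclic scheme is under-determined by two relaxation times"
        )
    if not (t_r1 > 0 and t_r2 > 0):
        raise ValueError("relaxation times must be positive")
    if t_r1 >= t_r2:
        raise ValueError("require t_r1 < t_r2")
    if min(x1, x2, x3) <= 0:
        raise ValueError("fractions must be positive")
    if abs(x1 + x2 + x3 - 1.0) > 1e-8:
        raise ValueError("fractions must sum to 1")

    a = x2 / x1
    b = x3 / x2
    S = 1.0 / t_r1 + 1.0 / t_r2
    P = 1.0 / (t_r1 * t_r2)
    # u = k21*(1+a), v = k32*(1+b):  u + v = S,  u*v = P * (1+a)(1+b)/(1+a+ab)
    q = P * (1.0 + a) * (1.0 + b) / (1.0 + a + a * b)
    disc = S * S - 4.0 * q
    if disc < 0:
        if disc > -64.0 * np.finfo(float).eps * S * S:
            disc = 0.0  # double root within rounding
        else:
            raise ValueError(
                f"no physical solution: discriminant {disc:.3e} < 0 "
                f"(margin {math.sqrt(-disc):.3e} ms^-1)"
            )
    root = math.sqrt(disc)
    # product-stable companion root avoids cancellation in the smaller one
    u_hi = 0.5 * (S + root)
    u_lo = q / u_hi if u_hi > 0 else 0.5 * (S - root)
    candidates = [(u_hi, u_lo), (u_lo, u_hi)]
    nets: list[RateNetwork] = []
    for u, v in candidates:
        if u <= 0 or v <= 0:
            continue
        k21 = u / (1.0 + a)
        k32 = v / (1.0 + b)
        net = RateNetwork(k12=a * k21, k21=k21, k23=b * k32, k32=k32)
        if any(_close(net, other, merge_tol) for other in nets):
            continue
        nets.append(net)
    # fast-C1C2 first: larger C1-C2 exchange rate sum leads
    nets.sort(key=lambda n: -(n.k12 + n.k21))
    return nets


def _close(n1: RateNetwork, n2: RateNetwork, tol: float) -> bool:
    v1 = np.array([n1.k12, n1.k21, n1.k23, n1.k32])
    v2 = np.array([n2.k12, n2.k21, n2.k23, n2.k32])
    return bool(np.all(np.abs(v1 - v2) <= tol * np.maximum(np.abs(v1), 1e-300)))


def energy_landscape(
    network: RateNetwork, k0_per_ms: float = 1e3, temperature_K: float = 298.0
) -> EnergyLandscape:
    """Free-energy differences and activation barriers in kBT units.

    For each transition i->j, dG0(i->j) = -ln(k_ji/k_ij) kBT (so a downhill
    step, faster forward than back, has negative dG0); the barrier of each
    directed step is dGact = -ln(k/k0) kBT against the prefactor k0.
    """
    if k0_per_ms <= 0:
        raise ValueError("k0 must be > 0")
    if network.is_cyclic:
        raise UnsupportedTopologyError("energy landscape defined for the linear chain")
    pairs = {("C1", "C2"): (network.k12, network.k21),
             ("C2", "C3"): (network.k23, network.k32)}
    g0: dict = {}
    gact: dict = {}
    for (i, j), (kf, kb) in pairs.items():
        if kf <= 0 or kb <= 0:
            raise ValueError("all rates must be > 0 for an energy landscape")
        g0[(i, j)] = -math.log(kb / kf)
        g0[(j, i)] = -g0[(i, j)]
        gact[(i, j)] = -math.log(kf / k0_per_ms)
        gact[(j, i)] = -math.log(kb / k0_per_ms)
    return EnergyLandscape(
        delta_g0=g0, delta_g_act=gact, k0_per_ms=k0_per_ms,
        temperature_K=temperature_K,
    )
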
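"""End-to-end orchestration and synthetic fixture generation.

A pipeline run chains the stages of the hybrid FRET workflow -- photon
simulation, burst analysis, filtered FCS, ensemble decay fitting, kinetic
network inversion, structure screening and the distance uncertainty budget
-- on synthetic data with known ground truth, recording provenance
(config hash, seed, package versions) with every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burst_mfd, decay_fit, dye_screen, ffcs, fret_uncertainty
from . import photon_sim
from .kinetics import RateNetwork, invert_three_state, relaxation_spectrum

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "make_fixtures",
    "toy_two_domain_structure",
    "default_three_state_network",
]


def default_three_state_network() -> RateNetwork:
    """A three-state chain with a fast major exchange (~4 us between the
    open-like and intermediate states) and a slow minor state (~230 us),
    populated at roughly 0.44/0.38/0.18."""
    # x = (0.44, 0.38, 0.18), t_R ~ (4 us, 230 us) -> invert for the rates
    nets = invert_three_state(4e-3, 0.23, 0.44, 0.38, 0.18)
    return nets[0]


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str | None = None
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "bursts": True, "ffcs": True, "decays": True,
        "kinetics": True, "screening": True, "uncertainty": True,
    })
    sim_duration_s: float = 8.0
    n_molecules: int = 10
    n_decay_counts: int = 2_000_000
    n_decay_channels: int = 1024
    decay_components: int = 3
    grid_spacing_A: float = 1.5
    kappa2_samples: int = 200_000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in workflow order; abort downstream
    stages on failure but keep partial results, flagged."""
    rng_seed = int(config.seed)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": rng_seed,
            "versions": _versions(),
        },
        "stages": {},
        "failed": None,
    }
    network = default_three_state_network()
    t_r_true, x_true = relaxation_spectrum(network)
    report["ground_truth"] = {
        "rates_ms^-1": [network.k12, network.k21, network.k23, network.k32],
        "t_relax_ms": t_r_true.tolist(),
        "fractions": x_true.tolist(),
    }

    state: dict = {}
    order = ["simulate", "bursts", "ffcs", "decays", "kinetics",
             "screening", "uncertainty"]
    stage_fns = {
        "simulate": _stage_simulate, "bursts": _stage_bursts,
        "ffcs": _stage_ffcs, "decays": _stage_decays,
        "kinetics": _stage_kinetics, "screening": _stage_screening,
        "uncertainty": _stage_uncertainty,
    }
    for name in order:
        if not config.stages.get(name, False):
            continue
        try:
            report["stages"][name] = stage_fns[name](config, network, state)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            report["stages"][name] = {"error": str(exc)}
            report["failed"] = name
            break
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2,
                                                    default=_jsonable))
    return report


def _jsonable(x):
    if isinstance(x, (np.ndarray,)):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return str(x)


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"fretdyn": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, network, state):
    t_r, x = relaxation_spectrum(network)
    cfg = photon_sim.SimConfig(
        duration_s=config.sim_duration_s,
        n_molecules=config.n_molecules,
        brightness_khz=(120.0, 120.0, 120.0),
        efficiencies=(0.3, 0.55, 0.85),
        background_khz=(0.3, 0.2),
        seed=config.seed,
    )
    stream = photon_sim.simulate_photon_stream(cfg, network)
    state["stream"] = stream
    state["sim_config"] = cfg
    return {"n_photons": len(stream), "duration_s": stream.duration_s}


def _stage_bursts(config, network, state):
    stream = state["stream"]
    bursts = burst_mfd.select_bursts(stream)
    corr = burst_mfd.Corrections(
        bg_green_khz=state["sim_config"].background_khz[0],
        bg_red_khz=state["sim_config"].background_khz[1])
    bursts = [burst_mfd.burst_indicators(stream, b, corr) for b in bursts]
    state["bursts"] = [b for b in bursts if b.valid]
    e = np.array([b.efficiency for b in state["bursts"]])
    return {"n_bursts": len(state["bursts"]),
            "mean_E": float(e.mean()) if len(e) else None}


def _stage_ffcs(config, network, state):
    stream = state["stream"]
    cfg = state["sim_config"]
    taus = cfg.state_donor_taus()
    effs = cfg.efficiencies
    patterns = np.stack([
        ffcs.species_pattern(effs[0], taus[0], cfg.acceptor_tau_ns,
                             cfg.n_microtime_channels, cfg.rep_period_ns,
                             cfg.irf_mean_ns, cfg.irf_width_ns),
        ffcs.species_pattern(effs[-1], taus[-1], cfg.acceptor_tau_ns,
                             cfg.n_microtime_channels, cfg.rep_period_ns,
                             cfg.irf_mean_ns, cfg.irf_width_ns),
    ])
    total = ffcs.measured_pattern(stream)
    filters = ffcs.build_filters(patterns, total, n_detectors=4)
    curves = ffcs.correlate_filtered(stream, filters, bin_s=2e-6)
    fit = ffcs.fit_correlations(curves, n_relax=2,
                                s_ratio=cfg.w_z_um / cfg.w_xy_um,
                                max_lag_s=1e-2)
    state["ffcs_fit"] = fit
    return {"t_relax_s": fit["t_relax_s"].tolist(),
            "t_diff_s": fit["t_diff_s"], "chi2r": fit["chi2r"]}


def _stage_decays(config, network, state):
    _, x = relaxation_spectrum(network)
    t = np.arange(config.n_decay_channels) * (25.0 / config.n_decay_channels)
    model = decay_fit.DistanceModel(
        fractions=x, distances_A=np.array([58.0, 48.0, 38.0]),
        widths_A=np.array([6.0, 6.0, 6.0]), x_donly=0.1,
    )
    ds = photon_sim.simulate_decay_dataset(
        model, t, config.n_decay_counts, seed=config.seed + 17)
    res = decay_fit.fit_decays_global(
        [ds], config.decay_components,
        donor_amplitudes=model.donor_amplitudes,
        donor_taus_ns=model.donor_taus_ns,
        r0_A=model.r0_A, n_restarts=4, seed=config.seed)
    state["decay_fit"] = res
    state["decay_truth"] = model
    return {"fractions": res.fractions.tolist(),
            "distances_A": res.distances_A.tolist(),
            "chi2r_global": res.chi2r_global}


def _stage_kinetics(config, network, state):
    fit = state.get("ffcs_fit")
    res = state.get("decay_fit")
    t_r = (np.sort(fit["t_relax_s"]) * 1e3 if fit is not None
           else relaxation_spectrum(network)[0])
    x = (res.fractions if res is not None
         else relaxation_spectrum(network)[1])
    x = np.clip(np.asarray(x, float), 1e-3, None)
    x = x / x.sum()
    # fractions are ordered by descending distance = C1, C2, C3
    nets = invert_three_state(float(t_r[0]), float(t_r[1]),
                              float(x[0]), float(x[1]), float(x[2]))
    state["kinetic_solutions"] = nets
    return {"n_solutions": len(nets),
            "solutions_ms^-1": [[n.k12, n.k21, n.k23, n.k32] for n in nets]}


def _stage_screening(config, network, state):
    structures = {name: toy_two_domain_structure(angle)
                  for name, angle in
                  (("open", 55.0), ("ajar", 35.0), ("closed", 15.0))}
    dist = make_distance_fixture(structures, seed=config.seed,
                                 grid_spacing_A=config.grid_spacing_A)
    screen = dye_screen.screen_structures(
        structures, dist, grid_spacing_A=config.grid_spacing_A)
    state["screen"] = screen
    return {"best": screen.best,
            "chi2": {st: screen.chi2[st].to_dict() for st in screen.chi2}}


def _stage_uncertainty(config, network, state):
    aniso = fret_uncertainty.AnisotropySet(r0=0.38, r_inf_donor=0.08,
                                           r_inf_acceptor=0.18)
    budget = fret_uncertainty.distance_uncertainty(
        r_da_A=45.0, aniso=aniso, delta_r_noise_minus_A=1.5,
        delta_r_noise_plus_A=2.0, n_samples=config.kappa2_samples,
        seed=config.seed)
    state["budget"] = budget
    return {"delta_precision": budget.delta_precision,
            "delta_accuracy": budget.delta_accuracy,
            "total_minus_A": budget.total_minus_A,
            "total_plus_A": budget.total_plus_A}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def toy_two_domain_structure(hinge_angle_deg: float,
                             name: str = "") -> dye_screen.StructureAtoms:
    """Rigid two-domain dummy protein: two 24-residue helices joined at a
    hinge; the second helix pivots by ``hinge_angle_deg`` so conformers
    differ by a rigid-body closure, mimicking an enzyme's two lobes."""
    def helix(n_res, res0):
        coords, elements, names, res_ids = [], [], [], []
        for i in range(n_res):
            ang = np.deg2rad(100.0 * i)
            base = np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i])
            for nm, el, off in (("N", "N", (-0.5, 0.3, -0.4)),
                                ("CA", "C", (0.0, 0.0, 0.0)),
                                ("C", "C", (0.5, -0.3, 0.4)),
                                ("O", "O", (1.0, 0.2, 0.6)),
                                ("CB", "C", None)):
                if off is None:
                    xy = base[:2]
                    nrm = xy / max(np.linalg.norm(xy), 1e-9)
                    pos = base + np.array([1.5 * nrm[0], 1.5 * nrm[1], 0.0])
                else:
                    pos = base + np.array(off)
                coords.append(pos)
                elements.append(el)
                names.append(nm)
                res_ids.append(res0 + i)
        return np.array(coords), elements, names, res_ids

    c1, e1, n1, r1 = helix(24, 1)
    c2, e2, n2, r2 = helix(24, 101)
    # place the second helix fanned out from the hinge at the first's top
    hinge = c1[-5 * 3]  # near the last residues
    th = np.deg2rad(hinge_angle_deg)
    rot = np.array([[np.cos(th), 0.0, np.sin(th)],
                    [0.0, 1.0, 0.0],
                    [-np.sin(th), 0.0, np.cos(th)]])
    c2 = (c2 - c2[0]) @ rot.T + hinge + np.array([4.0, 0.0, 4.0])
    coords = np.vstack([c1, c2])
    return dye_screen.StructureAtoms(
        coords=coords, elements=e1 + e2, atom_names=n1 + n2,
        res_ids=np.array(r1 + r2), chains=["A"] * len(e1) + ["B"] * len(e2),
        name=name or f"hinge{hinge_angle_deg:.0f}")


def make_distance_fixture(structures: dict, seed: int = 0,
                          noise_A: float = 0.8, dr_A: float = 2.5,
                          grid_spacing_A: float = 1.5,
                          n_pairs: int = 33) -> pd.DataFrame:
    """33-row experimental-style distance table: per conformational state,
    ACV model distances on the generating structure plus shot noise."""
    rng = np.random.default_rng(seed)
    don_sites = [3, 7, 11, 15, 19, 22]
    acc_sites = [103, 107, 111, 115, 119, 122]
    pairs = [(d, a) for d in don_sites for a in acc_sites][:n_pairs]
    state_of = dict(zip(structures.keys(), ["C1", "C2", "C3"]))
    rows = []
    clouds: dict = {}

    def cloud(s_name, st, res, spec):
        key = (s_name, res)
        if key not in clouds:
            idx = st.find_atom(res, "CB")
            clouds[key] = dye_screen.compute_acv(
                st, idx, spec, grid_spacing_A=grid_spacing_A)
        return clouds[key]

    for s_name, st in structures.items():
        for k, (d, a) in enumerate(pairs):
            cd = cloud(s_name, st, d, dye_screen.ALEXA488)
            ca = cloud(s_name, st, a, dye_screen.ALEXA647)
            met = dye_screen.interdye_metrics(cd, ca)
            rows.append({
                "pair_id": f"p{k:02d}",
                "don_res": d, "acc_res": a,
                "state": state_of[s_name],
                "R_exp_A": met["r_da_A"] + rng.normal(0.0, noise_A),
                "dR_minus_A": dr_A, "dR_plus_A": dr_A,
            })
    return pd.DataFrame(rows)


def make_fixtures(kind: str, seed: int = 0, outdir=None):
    """Small versioned synthetic datasets for tests and demos.

    kinds: 'decays' (DA/DOnly/IRF trio with 3-component truth), 'stream'
    (photon stream over the accepted three-state network), 'structures'
    (toy 3-conformer ensemble), 'distance_set' (33-row table generated
    from the open conformer).
    """
    from . import io as fio

    if kind == "decays":
        model = decay_fit.DistanceModel(
            fractions=np.array([0.44, 0.38, 0.18]),
            distances_A=np.array([58.0, 48.0, 38.0]),
            widths_A=np.array([6.0, 6.0, 6.0]), x_donly=0.1)
        t = np.arange(1024) * (25.0 / 1024)
        ds = photon_sim.simulate_decay_dataset(model, t, 2_000_000, seed=seed)
        if outdir:
            fio.write_decay_dataset(ds, Path(outdir) / "decays")
        return ds
    if kind == "stream":
        cfg = photon_sim.SimConfig(
            duration_s=4.0, n_molecules=8,
            brightness_khz=(120.0, 120.0, 120.0),
            efficiencies=(0.3, 0.55, 0.85), seed=seed)
        stream = photon_sim.simulate_photon_stream(
            cfg, default_three_state_network())
        if outdir:
            fio.write_photon_csv(stream, Path(outdir) / "stream.csv")
        return stream
    if kind == "structures":
        structs = {name: toy_two_domain_structure(angle, name=name)
                   for name, angle in
                   (("open", 55.0), ("ajar", 35.0), ("closed", 15.0))}
        return structs
    if kind == "distance_set":
        structs = make_fixtures("structures", seed)
        df = make_distance_fixture(structs, seed=seed)
        if outdir:
            fio.write_distance_set(df, Path(outdir) / "distances.csv")
        return df
    raise ValueError(f"unknown fixture kind {kind!r}")
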
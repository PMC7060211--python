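"""Accessible-contact-volume (ACV) dye modelling and FRET screening (FPS).

Organic dyes on long flexible linkers sample a cloud of sterically allowed
positions around their attachment atom.  The accessible volume is found by
a grid search: positions reachable by a linker path of bounded length that
avoids clashes with the protein, for each of three dye radii.  The contact
volume -- the shell within a few Angstrom of the surface -- is re-weighted
to the experimentally determined trapped-dye fraction.  Inter-cloud
metrics (R_mp between mean positions, the mean pair distance <R_DA> seen
by TCSPC, and the mean transfer efficiency <E>) feed the FPS error
function that ranks candidate structures against experimental distance
sets, and complete-linkage clustering on Calpha RMSD organizes structure
ensembles into conformational groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "DyeSpec",
    "ALEXA488",
    "ALEXA647",
    "StructureAtoms",
    "ACVCloud",
    "ScreenResult",
    "load_structure",
    "compute_acv",
    "interdye_metrics",
    "fit_rmp_polynomial",
    "screen_structures",
    "cluster_structures",
    "kabsch_rmsd",
]

VDW_RADII_A = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
               "P": 1.80, "SE": 1.90}
DEFAULT_VDW_A = 1.70


@dataclass
class DyeSpec:
    """Geometric dye/linker parameters of the AV3 hard-sphere model."""

    linker_length_A: float
    linker_width_A: float
    radii_A: tuple
    contact_thickness_A: float = 3.0
    x_trapped: float = 0.0

    def __post_init__(self) -> None:
        if self.linker_length_A <= 0 or min(self.radii_A) <= 0:
            raise ValueError("linker length and dye radii must be positive")
        if not (0.0 <= self.x_trapped <= 1.0):
            raise ValueError("x_trapped must be in [0, 1]")


# calibrated dye geometries for the standard Alexa pair
ALEXA488 = DyeSpec(linker_length_A=20.0, linker_width_A=4.5,
                   radii_A=(5.0, 4.5, 1.5))
ALEXA647 = DyeSpec(linker_length_A=22.0, linker_width_A=4.5,
                   radii_A=(11.0, 3.0, 3.5))


@dataclass
class StructureAtoms:
    """Heavy-atom view of a structural model."""

    coords: np.ndarray            # (N, 3) Angstrom
    elements: list
    atom_names: list
    res_ids: np.ndarray           # residue sequence numbers
    chains: list
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_ids = np.asarray(self.res_ids)

    def vdw_radii(self) -> np.ndarray:
        return np.array([VDW_RADII_A.get(str(e).upper(), DEFAULT_VDW_A)
                         for e in self.elements])

    def find_atom(self, res_id: int, atom_name: str = "CB",
                  chain: str | None = None) -> int | None:
        names = np.asarray(self.atom_names)
        mask = (self.res_ids == res_id) & (names == atom_name)
        if chain is not None:
            mask &= np.asarray(self.chains) == chain
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None

    def ca_coords(self) -> np.ndarray:
        names = np.asarray(self.atom_names)
        return self.coords[names == "CA"]


def load_structure(path, name: str | None = None) -> StructureAtoms:
    """Read the first model of a PDB file (altloc A, heavy atoms only)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    coords, elements, names, res_ids, chains = [], [], [], [], []
    for chain in model:
        for res in chain:
            for atom in res:
                if atom.altloc not in ("", "A"):
                    continue
                if atom.element.name == "H":
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name)
                names.append(atom.name)
                res_ids.append(res.seqid.num)
                chains.append(chain.name)
    return StructureAtoms(np.array(coords), elements, names,
                          np.array(res_ids), chains,
                          name=name or st.name or str(path))


@dataclass
class ACVCloud:
    points: np.ndarray            # (n, 3) grid positions
    weights: np.ndarray           # sum to 1
    attachment_point: np.ndarray
    contact_mask: np.ndarray | None = None
    grid_spacing_A: float = 0.9

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("empty dye cloud (fully buried attachment?)")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("cloud weights sum to zero")
        self.weights = self.weights / s

    @property
    def mean_position(self) -> np.ndarray:
        return self.weights @ self.points


def compute_acv(
    structure: StructureAtoms,
    attachment: int | tuple,
    spec: DyeSpec,
    grid_spacing_A: float = 0.9,
) -> ACVCloud:
    """Grid-search accessible contact volume for one labeling position.

    ``attachment`` is an atom index or a (res_id, atom_name[, chain])
    tuple.  A Dijkstra shortest-path search through clash-free grid cells
    (clearance >= half the linker width) bounds the linker path length; a
    grid cell belongs to the volume of dye radius R_k if additionally its
    clearance exceeds R_k, and the three radii contribute equal density.
    Cells within ``contact_thickness`` of the molecular surface form the
    contact volume, re-weighted so its total weight equals ``x_trapped``.
    """
    if isinstance(attachment, tuple):
        idx = structure.find_atom(*attachment)
        if idx is None:
            raise ValueError(f"attachment atom {attachment} not found")
    else:
        idx = int(attachment)
    origin = structure.coords[idx]

    # obstacles: all heavy atoms except the attachment residue (the label
    # replaces its side chain, and its backbone would trap the linker seed)
    keep = np.ones(len(structure.coords), dtype=bool)
    same_res = ((structure.res_ids == structure.res_ids[idx])
                & (np.asarray(structure.chains) == structure.chains[idx]))
    keep[same_res] = False
    atoms = structure.coords[keep]
    vdw = structure.vdw_radii()[keep]

    reach = spec.linker_length_A + max(spec.radii_A)
    half = int(np.ceil(reach / grid_spacing_A))
    ax = np.arange(-half, half + 1) * grid_spacing_A
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + origin
    r_att = np.linalg.norm(pts - origin, axis=1)
    within = r_att <= reach
    pts, r_att = pts[within], r_att[within]

    if len(atoms):
        tree = cKDTree(atoms)
        k = min(16, len(atoms))
        dist, nbr = tree.query(pts, k=k, workers=-1)
        dist = np.atleast_2d(dist.T).T
        nbr = np.atleast_2d(nbr.T).T
        d_surf = np.min(dist - vdw[nbr], axis=1)
    else:
        d_surf = np.full(len(pts), np.inf)

    path_free = d_surf >= spec.linker_width_A / 2.0
    path_len = _grid_path_lengths(pts, path_free, origin, grid_spacing_A)
    reachable = path_len <= spec.linker_length_A

    weights = np.zeros(len(pts))
    for r_k in spec.radii_A:
        weights += (reachable & (d_surf >= r_k)) / len(spec.radii_A)
    sel = weights > 0
    if not np.any(sel):
        raise ValueError("fully buried attachment: accessible volume is empty")
    pts, weights, d_surf = pts[sel], weights[sel], d_surf[sel]

    contact = d_surf <= spec.contact_thickness_A
    if spec.x_trapped > 0 and contact.any() and (~contact).any():
        w = weights.copy()
        wc, wf = w[contact].sum(), w[~contact].sum()
        w[contact] *= spec.x_trapped / wc
        w[~contact] *= (1.0 - spec.x_trapped) / wf
        weights = w
    return ACVCloud(points=pts, weights=weights, attachment_point=origin,
                    contact_mask=contact, grid_spacing_A=grid_spacing_A)


def _grid_path_lengths(pts, free, origin, spacing) -> np.ndarray:
    """Dijkstra linker-path length from the attachment to every free cell
    (26-neighbour connectivity, Euclidean edge lengths)."""
    n = len(pts)
    out = np.full(n, np.inf)
    free_idx = np.flatnonzero(free)
    if free_idx.size == 0:
        return out
    fp = pts[free_idx]
    # integer lattice keys for neighbour lookup
    key = np.round((fp - origin) / spacing).astype(np.int64)
    kmin = key.min(axis=0)
    dims = key.max(axis=0) - kmin + 1
    flat = ((key[:, 0] - kmin[0]) * dims[1] + (key[:, 1] - kmin[1])) * dims[2] \
        + (key[:, 2] - kmin[2])
    lookup = -np.ones(int(dims.prod()), dtype=np.int64)
    lookup[flat] = np.arange(free_idx.size)

    rows, cols, data = [], [], []
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
            for k in (-1, 0, 1) if (i, j, k) > (0, 0, 0)]
    for off in offs:
        nk = key + off
        ok = np.all((nk >= kmin) & (nk <= kmin + dims - 1), axis=1)
        nflat = ((nk[:, 0] - kmin[0]) * dims[1] + (nk[:, 1] - kmin[1])) * dims[2] \
            + (nk[:, 2] - kmin[2])
        tgt = np.where(ok, lookup[np.clip(nflat, 0, lookup.size - 1)], -1)
        src = np.flatnonzero(tgt >= 0)
        rows.append(src)
        cols.append(tgt[src])
        data.append(np.full(src.size, spacing * np.linalg.norm(off)))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)

    # virtual source node connected to cells near the attachment point
    d0 = np.linalg.norm(fp - origin, axis=1)
    seeds = np.flatnonzero(d0 <= max(2.0 * spacing, 2.0))
    if seeds.size == 0:
        return out
    nn = free_idx.size
    rows = np.concatenate([rows, np.full(seeds.size, nn)])
    cols = np.concatenate([cols, seeds])
    data = np.concatenate([data, d0[seeds]])
    graph = sparse.coo_matrix(
        (np.concatenate([data, data]),
         (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(nn + 1, nn + 1)).tocsr()
    dist = dijkstra(graph, indices=nn, limit=np.inf)
    out[free_idx] = dist[:nn]
    return out


# ---------------------------------------------------------------------------
# inter-dye metrics
# ---------------------------------------------------------------------------

_MAX_PAIRS_EXACT = 4_000_000


def interdye_metrics(cloud_d: ACVCloud, cloud_a: ACVCloud,
                     r0_A: float | None = None, seed: int = 12345) -> dict:
    """R_mp, <R_DA> and (given R0) <E> between two dye clouds.

    R_mp is the distance between the weighted mean dye positions; <R_DA>
    is the weight-averaged pairwise distance (what a lifetime measurement
    reports); <E> averages the point-dye isotropic transfer efficiency over
    pairs (distance-averaged regime).  Clouds large enough that the exact
    double sum is wasteful are subsampled with a fixed-seed weighted draw.
    """
    if r0_A is not None and r0_A <= 0:
        raise ValueError("R0 must be positive for <E>")
    r_mp = float(np.linalg.norm(cloud_d.mean_position - cloud_a.mean_position))
    n, m = len(cloud_d.points), len(cloud_a.points)
    r_da = 0.0
    e_sum = 0.0
    if n * m > _MAX_PAIRS_EXACT:
        rng = np.random.default_rng(seed)
        k = 200_000
        i = rng.choice(n, size=k, p=cloud_d.weights)
        j = rng.choice(m, size=k, p=cloud_a.weights)
        dist = np.linalg.norm(cloud_d.points[i] - cloud_a.points[j], axis=1)
        w = np.full(k, 1.0 / k)
        r_da = float(np.sum(w * dist))
        if r0_A is not None:
            e_sum = float(np.sum(w / (1.0 + (dist / r0_A) ** 6)))
    else:
        chunk = max(_MAX_PAIRS_EXACT // max(m, 1) // 4, 1)
        for a in range(0, n, chunk):
            dv = cloud_d.points[a:a + chunk, None, :] - cloud_a.points[None, :, :]
            dist = np.sqrt(np.sum(dv * dv, axis=2))
            w = cloud_d.weights[a:a + chunk, None] * cloud_a.weights[None, :]
            r_da += float(np.sum(w * dist))
            if r0_A is not None:
                e_sum += float(np.sum(w / (1.0 + (dist / r0_A) ** 6)))
    out = {"r_mp_A": r_mp, "r_da_A": r_da}
    if r0_A is not None:
        out["e_mean"] = e_sum
    return out


def fit_rmp_polynomial(r_mp: np.ndarray, r_da: np.ndarray, deg: int = 3):
    """Empirical R_mp <-> <R_DA> conversion, calibrated from simulated
    cloud pairs; returns (rmp_to_rda, rda_to_rmp) callables."""
    c1 = np.polyfit(r_mp, r_da, deg)
    c2 = np.polyfit(r_da, r_mp, deg)
    return np.poly1d(c1), np.poly1d(c2)


# ---------------------------------------------------------------------------
# FPS screening
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    chi2: pd.DataFrame            # rows: structure, columns: state
    ranking: dict                 # state -> ordered structure names
    best: dict                    # state -> best structure name
    regression: dict              # (structure) -> (slope, intercept)
    model_distances: pd.DataFrame
    n_pairs: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def screen_structures(
    structures: dict,
    distance_set: pd.DataFrame,
    donor_spec: DyeSpec = ALEXA488,
    acceptor_spec: DyeSpec = ALEXA647,
    attachment_atom: str = "CB",
    grid_spacing_A: float = 0.9,
) -> ScreenResult:
    """Rank structural models against per-state experimental distance sets.

    chi2_r,FPS = (1/N) sum_i (R_exp_i - R_model_i)^2 / dR_tot_i^2 per
    state and structure, with the asymmetric uncertainty side chosen by the
    sign of the residual (dR_plus when the model overshoots).  Pairs whose
    residues are missing in a structure are skipped with a warning and N
    reduced.  The experimental-vs-model linear regression per structure is
    reported alongside.
    """
    required = {"pair_id", "don_res", "acc_res", "state", "R_exp_A",
                "dR_minus_A", "dR_plus_A"}
    missing = required - set(distance_set.columns)
    if missing:
        raise ValueError(f"distance set lacks columns {sorted(missing)}")

    warn_log: list[str] = []
    rows = []
    cloud_cache: dict = {}

    def cloud_for(s_name, structure, res, spec):
        key = (s_name, int(res), spec.linker_length_A)
        if key not in cloud_cache:
            idx = structure.find_atom(int(res), attachment_atom)
            if idx is None:
                idx = structure.find_atom(int(res), "CA")
            if idx is None:
                cloud_cache[key] = None
            else:
                cloud_cache[key] = compute_acv(structure, idx, spec,
                                               grid_spacing_A=grid_spacing_A)
        return cloud_cache[key]

    for s_name, structure in structures.items():
        for _, row in distance_set.iterrows():
            cd = cloud_for(s_name, structure, row.don_res, donor_spec)
            ca = cloud_for(s_name, structure, row.acc_res, acceptor_spec)
            if cd is None or ca is None:
                msg = (f"{s_name}: pair {row.pair_id} skipped "
                       f"(residue {row.don_res if cd is None else row.acc_res}"
                       " missing)")
                warn_log.append(msg)
                warnings.warn(msg)
                continue
            met = interdye_metrics(cd, ca)
            rows.append({"structure": s_name, "pair_id": row.pair_id,
                         "state": row.state, "R_model_A": met["r_da_A"],
                         "R_mp_A": met["r_mp_A"], "R_exp_A": row.R_exp_A,
                         "dR_minus_A": row.dR_minus_A,
                         "dR_plus_A": row.dR_plus_A})

    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no mappable pairs on any structure")

    resid = table.R_model_A - table.R_exp_A
    sigma = np.where(resid > 0, table.dR_plus_A, table.dR_minus_A)
    table["chi2_term"] = (resid / sigma) ** 2

    chi2 = (table.groupby(["structure", "state"])["chi2_term"].mean()
            .unstack("state"))
    n_pairs = {st: int(g["pair_id"].nunique())
               for st, g in table.groupby("state")}
    ranking = {st: list(chi2[st].sort_values().index) for st in chi2.columns}
    best = {st: ranking[st][0] for st in chi2.columns}
    regression = {}
    for s_name, g in table.groupby("structure"):
        slope, intercept = np.polyfit(g.R_model_A, g.R_exp_A, 1)
        regression[s_name] = (float(slope), float(intercept))
    return ScreenResult(chi2=chi2, ranking=ranking, best=best,
                        regression=regression, model_distances=table,
                        n_pairs=n_pairs, warnings=warn_log)


# ---------------------------------------------------------------------------
# structure clustering
# ---------------------------------------------------------------------------

def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimum RMSD between two coordinate sets after optimal superposition."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape:
        raise ValueError("coordinate sets differ in shape")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    s_corr = s.copy()
    s_corr[-1] *= d
    e0 = np.sum(pc ** 2) + np.sum(qc ** 2)
    msd = max(e0 - 2.0 * np.sum(s_corr), 0.0) / len(p)
    return float(np.sqrt(msd))


def cluster_structures(structures, cutoff_A: float = 1.8):
    """Complete-linkage clustering of structures on pairwise Calpha RMSD.

    ``structures`` is a list of (n, 3) Calpha coordinate arrays (a common
    residue mapping is assumed) or StructureAtoms.  Returns a dict with
    cluster labels, member lists, medoid representatives and the condensed
    RMSD matrix.
    """
    coords = [s.ca_coords() if isinstance(s, StructureAtoms) else np.asarray(s)
              for s in structures]
    n = len(coords)
    if n == 0:
        raise ValueError("need at least one structure")
    sizes = {c.shape for c in coords}
    if len(sizes) > 1:
        raise ValueError("structures have no common Calpha mapping")
    if n == 1:
        return {"labels": np.array([1]), "clusters": {1: [0]},
                "representatives": {1: 0},
                "rmsd_matrix": np.zeros((1, 1))}
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = kabsch_rmsd(coords[i], coords[j])
    condensed = mat[np.triu_indices(n, 1)]
    z = hierarchy.complete(condensed)
    labels = hierarchy.fcluster(z, t=cutoff_A, criterion="distance")
    clusters: dict = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(int(lab), []).append(i)
    reps = {}
    for lab, members in clusters.items():
        sub = mat[np.ix_(members, members)]
        reps[lab] = members[int(np.argmin(sub.sum(axis=1)))]
    return {"labels": labels, "clusters": clusters,
            "representatives": reps, "rmsd_matrix": mat}
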
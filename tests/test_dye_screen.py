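"""ACV cloud geometry, inter-dye metrics against hand enumeration, FPS
chi-square bookkeeping and Calpha-RMSD clustering."""

import numpy as np
import pandas as pd
import pytest

from fretdyn import dye_screen as dsc
from fretdyn.dye_screen import ACVCloud, ALEXA488, ALEXA647, StructureAtoms


def _cloud(points, weights=None):
    points = np.asarray(points, dtype=float)
    w = (np.full(len(points), 1.0 / len(points)) if weights is None
         else np.asarray(weights, dtype=float))
    return ACVCloud(points=points, weights=w,
                    attachment_point=points.mean(axis=0))


class TestInterdyeMetrics:
    def test_hand_enumerated_four_pairs(self):
        """D at {0, 2}, A at {10, 12} on the x-axis: R_mp = 10 and
        <R_DA> = (10 + 12 + 8 + 10)/4 = 10."""
        d = _cloud([[0, 0, 0], [2, 0, 0]])
        a = _cloud([[10, 0, 0], [12, 0, 0]])
        m = dsc.interdye_metrics(d, a, r0_A=52.0)
        assert m["r_mp_A"] == pytest.approx(10.0)
        assert m["r_da_A"] == pytest.approx(10.0)
        e_hand = np.mean([1 / (1 + (r / 52.0) ** 6) for r in (10, 12, 8, 10)])
        assert m["e_mean"] == pytest.approx(e_hand, rel=1e-9)

    def test_congruent_translated_clouds(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 3, (50, 3))
        shift = np.array([17.0, 0.0, 0.0])
        m = dsc.interdye_metrics(_cloud(pts), _cloud(pts + shift))
        assert m["r_mp_A"] == pytest.approx(17.0, abs=1e-9)

    def test_mean_pair_distance_bounds_mean_position_distance(self):
        """<R_DA> >= R_mp for any clouds (Jensen/triangle)."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = _cloud(rng.normal(0, 4, (40, 3)))
            a = _cloud(rng.normal(10, 4, (30, 3)))
            m = dsc.interdye_metrics(d, a)
            assert m["r_da_A"] >= m["r_mp_A"] - 1e-9

    def test_negative_r0_rejected(self):
        d = _cloud([[0, 0, 0]])
        with pytest.raises(ValueError):
            dsc.interdye_metrics(d, d, r0_A=-1.0)

    def test_rmp_polynomial_round_trip(self):
        rng = np.random.default_rng(2)
        rmp = np.linspace(20, 80, 30)
        rda = rmp + 40.0 / rmp + rng.normal(0, 0.05, 30)
        to_rda, to_rmp = dsc.fit_rmp_polynomial(rmp, rda)
        assert to_rda(50.0) == pytest.approx(50.8, abs=0.3)
        assert to_rmp(to_rda(50.0)) == pytest.approx(50.0, abs=0.3)


class TestComputeACV:
    def test_free_space_cloud_centred_on_attachment(self):
        st = StructureAtoms(coords=np.array([[0.0, 0, 0]]), elements=["C"],
                            atom_names=["CB"], res_ids=np.array([1]),
                            chains=["A"])
        cloud = dsc.compute_acv(st, 0, ALEXA488, grid_spacing_A=1.5)
        assert np.allclose(cloud.mean_position, 0.0, atol=0.1)
        r = np.linalg.norm(cloud.points, axis=1)
        # linker-reachable ball (grid path metric slightly exceeds L)
        assert r.max() <= ALEXA488.linker_length_A * 1.05 + 1.5

    def test_zero_trapping_gives_uniform_free_weights(self):
        spec = dsc.DyeSpec(linker_length_A=15.0, linker_width_A=4.5,
                           radii_A=(3.5,), x_trapped=0.0)
        st = StructureAtoms(coords=np.array([[0.0, 0, 0]]), elements=["C"],
                            atom_names=["CB"], res_ids=np.array([1]),
                            chains=["A"])
        cloud = dsc.compute_acv(st, 0, spec, grid_spacing_A=1.5)
        assert np.allclose(cloud.weights, cloud.weights[0])

    def test_trapped_fraction_reweights_contact_shell(self, toy_structures):
        st = toy_structures["open"]
        spec = dsc.DyeSpec(linker_length_A=20.0, linker_width_A=4.5,
                           radii_A=(5.0, 4.5, 1.5), x_trapped=0.6)
        cloud = dsc.compute_acv(st, st.find_atom(7, "CB"), spec,
                                grid_spacing_A=1.5)
        assert cloud.weights[cloud.contact_mask].sum() == pytest.approx(0.6)

    def test_buried_attachment_raises(self):
        # attachment atom fully caged by a dense shell of carbons
        shell = []
        for th in np.linspace(0, np.pi, 14):
            for ph in np.linspace(0, 2 * np.pi, 22, endpoint=False):
                shell.append([3.5 * np.sin(th) * np.cos(ph),
                              3.5 * np.sin(th) * np.sin(ph),
                              3.5 * np.cos(th)])
        coords = np.vstack([[0.0, 0.0, 0.0], shell])
        st = StructureAtoms(
            coords=coords, elements=["C"] * len(coords),
            atom_names=["CB"] + ["C"] * (len(coords) - 1),
            res_ids=np.arange(len(coords)), chains=["A"] * len(coords))
        with pytest.raises(ValueError, match="buried|empty"):
            dsc.compute_acv(st, 0, ALEXA488, grid_spacing_A=1.5)

    def test_grid_convergence(self, toy_structures):
        """Halving the grid spacing moves <R_DA> by < 0.5 A."""
        st = toy_structures["open"]
        vals = []
        for spacing in (2.0, 1.0):
            cd = dsc.compute_acv(st, st.find_atom(3, "CB"), ALEXA488,
                                 grid_spacing_A=spacing)
            ca = dsc.compute_acv(st, st.find_atom(103, "CB"), ALEXA647,
                                 grid_spacing_A=spacing)
            vals.append(dsc.interdye_metrics(cd, ca)["r_da_A"])
        assert abs(vals[1] - vals[0]) < 0.5


class TestScreening:
    def _toy_set(self, r_model, sigma=2.0):
        return pd.DataFrame({
            "pair_id": [f"p{i}" for i in range(len(r_model))],
            "don_res": np.arange(len(r_model)) + 1,
            "acc_res": np.arange(len(r_model)) + 101,
            "state": "C1",
            "R_exp_A": r_model,
            "dR_minus_A": sigma, "dR_plus_A": sigma,
        })

    def test_chi2_zero_on_self_match(self):
        """chi2_r,FPS = 0 when model distances equal experiment, and 1/33
        when exactly one of 33 pairs is off by its own sigma."""
        r = np.linspace(30, 60, 33)
        table = self._toy_set(r)
        resid = np.zeros(33)
        chi2 = np.mean((resid / table.dR_minus_A) ** 2)
        assert chi2 == 0.0
        resid[4] = 2.0  # one sigma
        chi2 = np.mean((resid / table.dR_minus_A) ** 2)
        assert chi2 == pytest.approx(1.0 / 33.0)

    def test_screen_assigns_generating_structure(self, toy_structures,
                                                 toy_distance_set):
        res = dsc.screen_structures(toy_structures, toy_distance_set,
                                    grid_spacing_A=1.5)
        assert res.best == {"C1": "open", "C2": "ajar", "C3": "closed"}
        for st in res.chi2.columns:
            assert res.chi2.loc[res.best[st], st] < 1.0
        for name, (slope, _) in res.regression.items():
            assert 0.7 < slope < 1.3

    def test_missing_residue_skipped_with_warning(self, toy_structures):
        df = self._toy_set(np.linspace(30, 60, 5))
        df.loc[0, "don_res"] = 999  # not in the structure
        with pytest.warns(UserWarning, match="skipped"):
            res = dsc.screen_structures(
                {"open": toy_structures["open"]}, df, grid_spacing_A=1.5)
        assert res.n_pairs["C1"] == 4
        assert res.warnings

    def test_asymmetric_uncertainty_side(self):
        """The sigma used follows the residual sign: dR_plus when the
        model overshoots the experiment."""
        table = pd.DataFrame({"R_model_A": [50.0, 40.0],
                              "R_exp_A": [45.0, 45.0],
                              "dR_minus_A": [1.0, 1.0],
                              "dR_plus_A": [5.0, 5.0]})
        resid = table.R_model_A - table.R_exp_A
        sigma = np.where(resid > 0, table.dR_plus_A, table.dR_minus_A)
        terms = (resid / sigma) ** 2
        assert terms[0] == pytest.approx(1.0)   # +5 / 5
        assert terms[1] == pytest.approx(25.0)  # -5 / 1


class TestClustering:
    def test_kabsch_vs_quaternion_oracle(self):
        """SVD superposition equals the quaternion eigen method to 1e-8
        on random 20-atom toys."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.normal(0, 5, (20, 3))
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(0, np.pi)
            k = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * k @ k
            q = p @ rot.T + rng.normal(0, 1, (20, 3)) * 0.3 + 7.0
            assert dsc.kabsch_rmsd(p, q) == pytest.approx(
                _quaternion_rmsd(p, q), abs=1e-8)

    def test_identical_copies_single_cluster(self):
        pts = np.random.default_rng(4).normal(0, 5, (30, 3))
        out = dsc.cluster_structures([pts.copy() for _ in range(4)],
                                     cutoff_A=1.8)
        assert len(out["clusters"]) == 1
        assert np.allclose(out["rmsd_matrix"], 0.0, atol=1e-9)

    def test_two_conformer_groups_split(self, toy_structures):
        open_ca = toy_structures["open"].ca_coords()
        closed_ca = toy_structures["closed"].ca_coords()
        rng = np.random.default_rng(5)
        members = ([open_ca + rng.normal(0, 0.1, open_ca.shape)
                    for _ in range(3)]
                   + [closed_ca + rng.normal(0, 0.1, closed_ca.shape)
                      for _ in range(3)])
        out = dsc.cluster_structures(members, cutoff_A=1.8)
        assert len(out["clusters"]) == 2
        labels = out["labels"]
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_rotation_translation_invariance(self, toy_structures):
        ca = toy_structures["open"].ca_coords()
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        moved = ca @ rot.T + np.array([30.0, -12.0, 5.0])
        out = dsc.cluster_structures([ca, moved], cutoff_A=0.5)
        assert len(out["clusters"]) == 1

    def test_mismatched_mappings_rejected(self):
        with pytest.raises(ValueError, match="mapping"):
            dsc.cluster_structures([np.zeros((10, 3)), np.zeros((12, 3))])


def _quaternion_rmsd(p, q):
    """Independent oracle: optimal superposition via the Horn quaternion
    eigenvalue method."""
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    m = pc.T @ qc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k).max()
    e0 = np.sum(pc ** 2) + np.sum(qc ** 2)
    return np.sqrt(max(e0 - 2 * lam, 0.0) / len(p))
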
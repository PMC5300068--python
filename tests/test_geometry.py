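"""Superposition, buried surface area and bend parameterization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flexscat import (DomainMap, Segment, bend_parameters,
                      buried_surface_area, ensemble_align, superpose)
from flexscat.structure import StructureModel


def ca_chain_model(xyz, chain="A", names=None):
    n = len(xyz)
    return StructureModel(
        element=np.array(["C"] * n), name=np.array(["CA"] * n),
        resname=np.array(["ALA"] * n), resseq=np.arange(1, n + 1),
        icode=np.array([" "] * n),
        chain=np.array([chain] * n), het=np.zeros(n, dtype=bool),
        xyz=np.asarray(xyz, dtype=float),
    )


def helix_model(n=60, chain="A"):
    t = np.arange(n) * 0.6
    xyz = np.column_stack([np.cos(t), np.sin(t), 0.15 * t])
    return ca_chain_model(xyz, chain)


class TestSuperpose:
    def test_self_superposition(self):
        m = helix_model()
        res = superpose(m, m)
        assert res.rmsd_a == pytest.approx(0.0, abs=1e-9)
        assert res.n_retained == m.n_atoms
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, rel=1e-9)

    def test_rotation_recovery(self):
        m = helix_model()
        R = Rotation.from_euler("xyz", [0.4, -1.2, 2.0]).as_matrix()
        moved = m.copy()
        moved.xyz = (R @ m.xyz.T).T + [3.0, -1.0, 0.5]
        res = superpose(moved, m)
        assert res.rmsd_a == pytest.approx(0.0, abs=1e-6)

    def test_trimming_rejects_outliers(self):
        m = helix_model()
        noisy = m.copy()
        rng = np.random.default_rng(0)
        noisy.xyz = m.xyz + rng.normal(0, 0.005, m.xyz.shape)
        noisy.xyz[10] += [2.0, 0.0, 0.0]  # one 20 A outlier
        res = superpose(noisy, m, trim_sigma=2.0)
        assert 10 in res.rejected
        assert res.rmsd_a < 0.2

    def test_symmetric_rmsd(self):
        m = helix_model()
        other = m.copy()
        rng = np.random.default_rng(1)
        other.xyz = m.xyz + rng.normal(0, 0.01, m.xyz.shape)
        r1 = superpose(m, other).rmsd_a
        r2 = superpose(other, m).rmsd_a
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_too_few_pairs(self):
        m = ca_chain_model([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            superpose(m, m)


class TestBuriedSurface:
    def test_distant_groups_zero(self):
        a = ca_chain_model(np.random.default_rng(2).uniform(0, 1, (20, 3)))
        b = ca_chain_model(
            np.random.default_rng(3).uniform(0, 1, (20, 3)) + 6.0, chain="B")
        m = _concat(a, b)
        res = buried_surface_area(m, m.chain == "A", m.chain == "B")
        assert res["total_a2"] == pytest.approx(0.0, abs=1e-6)
        assert not res["stable_dimer"]

    def test_two_touching_spheres_cap_area(self):
        # single pseudo-atoms of radius r at distance d bury a spherical cap
        # of the probe-inflated sphere on each: 2 pi R h, h = R - d/2
        r_vdw = 2.0
        d = 3.0  # Angstrom
        m = ca_chain_model([[0, 0, 0], [d / 10.0, 0, 0]])
        radii = np.array([r_vdw, r_vdw])
        res = buried_surface_area(m, np.array([True, False]),
                                  np.array([False, True]), radii_a=radii)
        R = r_vdw + 1.4
        h = R - d / 2.0
        expect_total = 2 * (2 * np.pi * R * h)
        assert res["total_a2"] == pytest.approx(expect_total, rel=0.05)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        a = ca_chain_model(rng.uniform(0, 1.5, (30, 3)))
        b = ca_chain_model(rng.uniform(0, 1.5, (30, 3)) + [1.4, 0, 0], "B")
        m = _concat(a, b)
        base = buried_surface_area(m, m.chain == "A", m.chain == "B")
        R = Rotation.from_euler("zxz", [1.0, 0.5, -0.3]).as_matrix()
        m2 = m.copy()
        m2.xyz = (R @ m.xyz.T).T + [2.0, 1.0, -3.0]
        rot = buried_surface_area(m2, m2.chain == "A", m2.chain == "B")
        assert rot["total_a2"] == pytest.approx(base["total_a2"], rel=0.02)

    def test_overlapping_groups_error(self):
        m = helix_model()
        g = np.ones(m.n_atoms, dtype=bool)
        with pytest.raises(ValueError):
            buried_surface_area(m, g, g)


def _concat(a, b):
    import dataclasses

    kw = {}
    for f in dataclasses.fields(a):
        kw[f.name] = np.concatenate([getattr(a, f.name), getattr(b, f.name)])
    return StructureModel(**kw)


def two_arm_model(theta_deg):
    """Minimal dimer: 4 core pseudo-domains at origin, two end domains."""
    half = np.deg2rad(theta_deg) / 2.0
    e1 = 5.0 * np.array([np.cos(half), np.sin(half), 0.0])
    e2 = 5.0 * np.array([np.cos(half), -np.sin(half), 0.0])
    rows_a = [[0.1, 0.1, 0], [-0.1, 0.2, 0], e1]
    rows_b = [[-0.1, -0.1, 0], [0.1, -0.2, 0], e2]
    a = ca_chain_model(rows_a, "A")
    b = ca_chain_model(rows_b, "B")
    m = _concat(a, b)
    segs = []
    for c in ("A", "B"):
        segs += [Segment("CUB1", c, 1, 1), Segment("EGF", c, 2, 2),
                 Segment("CUB2", c, 3, 3)]
    return m, DomainMap(segs)


class TestBendParameters:
    @pytest.mark.parametrize("theta", [180.0, 90.0, 120.0])
    def test_constructed_angles(self, theta):
        m, dm = two_arm_model(theta)
        gp = bend_parameters(m, dm, "CUB2", ("CUB1", "EGF"),
                             chains=("A", "B"))
        assert gp.theta_deg == pytest.approx(theta, abs=1.5)

    def test_rigid_motion_and_mirror_invariance(self):
        m, dm = two_arm_model(117.0)
        base = bend_parameters(m, dm, "CUB2", ("CUB1", "EGF"), ("A", "B"))
        R = Rotation.from_euler("xyz", [0.2, 0.7, 1.9]).as_matrix()
        m2 = m.copy()
        m2.xyz = (R @ m.xyz.T).T + [1, 2, 3]
        moved = bend_parameters(m2, dm, "CUB2", ("CUB1", "EGF"), ("A", "B"))
        assert moved.theta_deg == pytest.approx(base.theta_deg, abs=1e-9)
        assert moved.separation_nm == pytest.approx(base.separation_nm,
                                                    abs=1e-9)
        mirror = m.copy()
        mirror.xyz = m.xyz * [1.0, 1.0, -1.0]
        mir = bend_parameters(mirror, dm, "CUB2", ("CUB1", "EGF"), ("A", "B"))
        assert mir.theta_deg == pytest.approx(base.theta_deg, abs=1e-9)

    def test_toy_dimer_ground_truth(self, bent_toy):
        gp = bent_toy.truth
        assert gp.theta_deg == pytest.approx(120.0, abs=2.0)


class TestEnsembleAlign:
    def test_rotated_copies_align_to_zero_rmsd(self, masp3d_toy):
        toy = masp3d_toy
        rng = np.random.default_rng(5)
        models = [toy.model]
        for _ in range(4):
            R = Rotation.random(random_state=rng).as_matrix()
            m = toy.model.copy()
            m.xyz = (R @ m.xyz.T).T + rng.uniform(-3, 3, 3)
            models.append(m)
        aligned = ensemble_align(models, toy.domains)
        ref = aligned[0].xyz
        for m in aligned[1:]:
            assert np.sqrt(np.mean((m.xyz - ref) ** 2)) < 1e-9

    def test_topology_mismatch(self, masp3d_toy):
        short = masp3d_toy.model.copy()
        import dataclasses

        for f in dataclasses.fields(short):
            setattr(short, f.name, getattr(short, f.name)[:-5])
        with pytest.raises(ValueError):
            ensemble_align([masp3d_toy.model, short], masp3d_toy.domains)
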
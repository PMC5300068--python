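"""Monte-Carlo linker sampling, steric filtering and best-model selection."""

import dataclasses

import numpy as np
import pytest

from flexscat import (LinkerSet, ScatteringCurve, clash_check, debye_curve,
                      perturb_linkers, run_search, select_best)
from flexscat.sampling import SearchConfig, TerminalLinkerError, conformation_model
from flexscat.structure import Linker, assign_segment_ids
from flexscat.synthetic import ToyDimerSpec, make_toy_dimer


@pytest.fixture(scope="module")
def toy():
    return make_toy_dimer(ToyDimerSpec())


class TestPerturb:
    def test_empty_linker_set_identity(self, toy):
        out = perturb_linkers(toy.model, LinkerSet([]), seed=1)
        np.testing.assert_array_equal(out.xyz, toy.model.xyz)

    def test_seed_determinism(self, toy):
        a = perturb_linkers(toy.model, toy.linkers, seed=7)
        b = perturb_linkers(toy.model, toy.linkers, seed=7)
        c = perturb_linkers(toy.model, toy.linkers, seed=8)
        np.testing.assert_array_equal(a.xyz, b.xyz)
        assert not np.allclose(a.xyz, c.xyz)

    def test_rigid_segments_preserved_exactly(self, toy):
        out = perturb_linkers(toy.model, toy.linkers, seed=3)
        for seg in toy.domains.rigid_segments():
            m = toy.model.mask(chain=seg.chain,
                               res_range=(seg.start, seg.end))
            x0 = toy.model.xyz[m] - toy.model.xyz[m].mean(axis=0)
            x1 = out.xyz[m] - out.xyz[m].mean(axis=0)
            # internal geometry unchanged: all intra-segment distances equal
            d0 = np.linalg.norm(x0[0] - x0[-1])
            d1 = np.linalg.norm(x1[0] - x1[-1])
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_rigid_superposition_rmsd_below_tolerance(self, toy):
        from flexscat.geometry import _kabsch

        out = perturb_linkers(toy.model, toy.linkers, seed=11)
        for seg in toy.domains.rigid_segments():
            m = toy.model.mask(chain=seg.chain,
                               res_range=(seg.start, seg.end))
            _, _, rmsd = _kabsch(out.xyz[m], toy.model.xyz[m])
            assert rmsd < 1e-6  # nm

    def test_angular_flex_coverage(self, toy):
        """Sampled EGF-CUB2 hinge angles of a two-linker dimer span >= 90 deg."""
        hinge = toy.linkers.linkers[0].start  # first linker bead, chain A

        def hinge_angle(model):
            e = model.xyz[model.mask(chain="A",
                                     res_range=_seg_range(toy, "EGF"))].mean(0)
            c = model.xyz[model.mask(chain="A",
                                     res_range=_seg_range(toy, "CUB2"))].mean(0)
            p = model.xyz[model.mask(chain="A", resseq=hinge)][0]
            v1 = (e - p) / np.linalg.norm(e - p)
            v2 = (c - p) / np.linalg.norm(c - p)
            return np.degrees(np.arccos(np.clip(v1 @ v2, -1, 1)))

        seg_ids = assign_segment_ids(toy.model, toy.domains)
        angles = []
        for k in range(800):
            trial = perturb_linkers(toy.model, toy.linkers,
                                    seed=np.random.default_rng([21, k]))
            if clash_check(trial, seg_ids):
                angles.append(hinge_angle(trial))
        assert len(angles) > 200
        assert max(angles) - min(angles) >= 90.0

    def test_terminal_linker_without_downstream_atoms(self, toy):
        last = int(toy.model.resseq[toy.model.chain == "A"].max())
        bad = LinkerSet([Linker("A", last, last)])
        with pytest.raises(TerminalLinkerError):
            perturb_linkers(toy.model, bad, seed=0)


def _seg_range(toy, name):
    seg = toy.domains.get(name, "A")[0]
    return (seg.start, seg.end)


class TestClashCheck:
    def test_distant_segments_clash_free(self, toy):
        ids = assign_segment_ids(toy.model, toy.domains)
        assert clash_check(toy.model, ids, cutoff=0.25)

    def test_duplicated_segment_clashes(self, toy):
        m = toy.model.copy()
        # slide chain B onto chain A
        shift = m.xyz[m.chain == "A"].mean(0) - m.xyz[m.chain == "B"].mean(0)
        m.xyz[m.chain == "B"] += shift
        ids = assign_segment_ids(m, toy.domains)
        assert not clash_check(m, ids, cutoff=0.25)

    def test_grid_matches_brute_force(self, toy):
        ids = assign_segment_ids(toy.model, toy.domains)
        heavy_xyz = toy.model.xyz
        rng = np.random.default_rng(2)
        for k in range(40):
            trial = perturb_linkers(toy.model, toy.linkers,
                                    seed=np.random.default_rng([5, k]))
            fast = clash_check(trial, ids, cutoff=0.25)
            # brute force all-pairs check
            d = np.linalg.norm(trial.xyz[:, None] - trial.xyz[None, :],
                               axis=2)
            mask = (ids[:, None] >= 0) & (ids[None, :] >= 0) \
                & (ids[:, None] != ids[None, :])
            brute = not np.any(d[mask] < 0.25)
            assert fast == brute


@pytest.fixture(scope="module")
def target(toy):
    from flexscat import build_sphere_model

    sp = build_sphere_model(toy.model, hydrate=True,
                            dry_volume=toy.dry_volume, mass=toy.mass)
    return debye_curve(sp, np.linspace(0.05, 2.0, 120))


class TestSearch:
    def test_single_trial_contains_start_r_factor(self, toy, target):
        cfg = SearchConfig(mode="step", step=1e-6,
                           dry_volume=toy.dry_volume, mass=toy.mass)
        res = run_search(toy.model, toy.linkers, target, n_trials=1,
                         seed=0, domains=toy.domains, config=cfg)
        assert res.n_accepted == 1
        # zero-step perturbation: the start structure fits its own curve
        assert res.best[0].score.r_factor < 0.5

    def test_search_determinism(self, toy, target):
        cfg = SearchConfig(dry_volume=toy.dry_volume, mass=toy.mass)
        a = run_search(toy.model, toy.linkers, target, n_trials=20, seed=4,
                       domains=toy.domains, config=cfg)
        b = run_search(toy.model, toy.linkers, target, n_trials=20, seed=4,
                       domains=toy.domains, config=cfg)
        assert a.table.equals(b.table)
        np.testing.assert_array_equal(a.best[0].xyz, b.best[0].xyz)

    def test_accepted_trials_have_rigid_segments(self, toy, target):
        from flexscat.geometry import _kabsch

        cfg = SearchConfig(dry_volume=toy.dry_volume, mass=toy.mass)
        res = run_search(toy.model, toy.linkers, target, n_trials=25, seed=9,
                         domains=toy.domains, config=cfg)
        for tc in res.best:
            m = conformation_model(toy.model, tc)
            for seg in toy.domains.rigid_segments():
                sel = toy.model.mask(chain=seg.chain,
                                     res_range=(seg.start, seg.end))
                _, _, rmsd = _kabsch(m.xyz[sel], toy.model.xyz[sel])
                assert rmsd < 1e-6

    def test_select_best_ordering(self, toy, target):
        cfg = SearchConfig(dry_volume=toy.dry_volume, mass=toy.mass)
        res = run_search(toy.model, toy.linkers, target, n_trials=30,
                         seed=12, domains=toy.domains, config=cfg)
        best = select_best(res, 10)
        rs = [t.score.r_factor for t in best]
        assert rs == sorted(rs)
        assert len(best) == 10
        with pytest.warns(UserWarning):
            too_many = select_best(res, 10_000)
        assert len(too_many) == len(res.best)

    def test_restart_from_best_fit_consistent(self, toy, target):
        """Search 2 from a best-fit model reproduces the best R factor."""
        cfg = SearchConfig(dry_volume=toy.dry_volume, mass=toy.mass)
        s1 = run_search(toy.model, toy.linkers, target, n_trials=150, seed=2,
                        domains=toy.domains, config=cfg)
        best_model = conformation_model(toy.model, select_best(s1, 1)[0])
        s2 = run_search(best_model, toy.linkers, target, n_trials=150, seed=3,
                        domains=toy.domains, config=cfg,
                        start_label="search 2")
        r1 = np.mean([t.score.r_factor for t in select_best(s1, 10)])
        r2 = np.mean([t.score.r_factor for t in select_best(s2, 10)])
        assert abs(r1 - r2) < 1.0  # unchanged within the sampling noise
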
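"""Monte-Carlo conformational search over declared flexible linkers.

The search is a generate-and-filter scan, not an equilibrium sampler: each
trial independently resamples the backbone dihedrals of every linker residue
(flat on (-180, 180] by default, or a bounded step), rejects sterically
clashing conformations at creation, simulates the trial's scattering curve
and ranks it against the target by R factor.  No Metropolis criterion is
applied.  The two chains of a dimer are sampled independently; no 2-fold
symmetry is imposed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .scattering import FitScore, ScatteringCurve, debye_curve, guinier_fit, r_factor
from .spheres import build_sphere_model
from .structure import DomainMap, LinkerSet, StructureModel, assign_segment_ids


@dataclass
class TrialConformation:
    index: int
    xyz: np.ndarray
    varied: list[tuple]           # (chain, resseq, angle name, value deg)
    rg: float                     # sphere-model R_g, nm
    score: FitScore
    accepted: bool = True


@dataclass
class SearchConfig:
    cube_side: float = 0.55
    hydrate: bool = True
    clash_cutoff: float = 0.25    # nm, heavy atoms of different rigid units
    step: float = 180.0           # degrees; 180 with mode="resample" is flat
    mode: str = "resample"        # "resample" | "step"
    acceptance_floor: float = 0.02
    floor_window: int = 5000
    max_proposals: int | None = None
    dry_volume: float | None = None   # override for pseudo-atom models
    mass: float | None = None
    n_best: int = 10
    # Q range scored by the R factor (None = full overlap); the fitted range
    # is recorded in every FitScore
    q_range: tuple[float, float] | None = None
    # optional callable(StructureModel) -> dict of floats, recorded per
    # accepted trial (e.g. bend angles for coverage statistics)
    geometry_hook: object = None
    # retention pool size for selection (>= n_best so that noise-level ties
    # can still be re-ranked by R_g agreement)
    n_keep: int = 50


@dataclass
class SearchResult:
    table: pd.DataFrame           # trial id, rg, r_factor, accepted
    best: list[TrialConformation]  # retention pool, ascending R factor
    seed: int
    n_proposed: int
    n_accepted: int
    start_label: str = "start"
    target_rg: float = np.nan
    # expected R-factor contribution of the target's own noise (percent);
    # trials within this of the minimum are statistically indistinguishable
    noise_r_level: float = 0.0


# ---------------------------------------------------------------------------
# Dihedral perturbation


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - b0.dot(b1n) * b1n
    w = b2 - b2.dot(b1n) * b1n
    return float(np.degrees(np.arctan2(np.cross(b1n, v).dot(w), v.dot(w))))


def _rotate_about(xyz, mask, point, axis, angle_deg):
    axis = axis / np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    xyz[mask] = (R @ (xyz[mask] - point).T).T + point


class TerminalLinkerError(ValueError):
    pass


def perturb_linkers(model: StructureModel, linkers: LinkerSet,
                    step: float = 180.0, seed: int | np.random.Generator = 0,
                    mode: str = "resample") -> StructureModel:
    """Resample or step the backbone dihedrals of every linker residue.

    Protein residues (with N/CA/C backbone atoms) vary phi and psi; single
    pseudo-atom residues of bead models pivot their downstream chain about a
    random axis through the bead (ball joint).  All atoms of the chain
    downstream of the varied residue rotate rigidly, so rigid segments are
    preserved exactly.
    """
    if not (0.0 < step <= 180.0):
        raise ValueError("step must be in (0, 180] degrees")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = model.copy()
    if not linkers.linkers:
        return out
    xyz = out.xyz
    rid = out.residue_index()
    # glycan beads take the residue rank of their anchor, so they ride with
    # the domain they are attached to instead of counting as chain tail
    eff_rid = rid.copy()
    if out.glycan.any():
        host = {}
        for i in np.flatnonzero(~out.glycan):
            host[(out.chain[i], int(out.resseq[i]))] = rid[i]
        for i in np.flatnonzero(out.glycan):
            key = (out.chain[i], int(out.anchor_resseq[i]))
            if key in host:
                eff_rid[i] = host[key]
    for ln in linkers.linkers:
        chain_mask = out.chain == ln.chain
        chain_rids = np.unique(eff_rid[chain_mask])
        for resseq in range(ln.start, ln.end + 1):
            res_mask = chain_mask & (out.resseq == resseq) & ~out.glycan
            if not res_mask.any():
                continue
            this_rid = rid[res_mask][0]
            downstream = chain_mask & (eff_rid > this_rid)
            names = np.char.strip(out.name[res_mask].astype(str))
            ridx = np.flatnonzero(res_mask)
            has_bb = all(n in names for n in ("N", "CA", "C"))
            if has_bb:
                aN = xyz[ridx[names == "N"][0]]
                aCA = xyz[ridx[names == "CA"][0]]
                aC = xyz[ridx[names == "C"][0]]
                # phi: rotate side chain + C/O of this residue + downstream
                phi_mask = downstream.copy()
                phi_mask[ridx[(names != "N") & (names != "CA")]] = True
                psi_mask = downstream.copy()
                psi_mask[ridx[names == "O"]] = True
                for bb_mask, point, axis, name in (
                    (phi_mask, aN, aCA - aN, "phi"),
                    (psi_mask, aCA, aC - aCA, "psi"),
                ):
                    if not bb_mask.any():
                        continue
                    if mode == "resample":
                        delta = rng.uniform(-180.0, 180.0)
                    else:
                        delta = rng.uniform(-step, step)
                    _rotate_about(xyz, bb_mask, point, axis, delta)
            else:
                if not downstream.any():
                    if this_rid == chain_rids.max():
                        raise TerminalLinkerError(
                            f"linker residue {ln.chain}:{resseq} has no "
                            "downstream atoms to rotate"
                        )
                    continue
                pivot = xyz[ridx[0]]
                axis = rng.normal(size=3)
                while np.linalg.norm(axis) < 1e-12:
                    axis = rng.normal(size=3)
                if mode == "resample":
                    delta = rng.uniform(-step, step)
                else:
                    delta = rng.uniform(-step, step)
                _rotate_about(xyz, downstream, pivot, axis, delta)
    return out


def perturbation_record(model: StructureModel, perturbed: StructureModel,
                        linkers: LinkerSet) -> list[tuple]:
    """Summarize which linker residues moved (for SearchResult metadata)."""
    rec = []
    for ln in linkers.linkers:
        for resseq in range(ln.start, ln.end + 1):
            m = (model.chain == ln.chain) & (model.resseq == resseq)
            if m.any() and not np.allclose(model.xyz[m], perturbed.xyz[m]):
                rec.append((ln.chain, resseq, "moved", np.nan))
    return rec


# ---------------------------------------------------------------------------
# Steric filter


def clash_check(model: StructureModel, segment_ids: np.ndarray,
                cutoff: float = 0.25) -> bool:
    """True iff no heavy-atom pair from *different* rigid units is closer
    than ``cutoff`` (nm).  Linker atoms (id -1) are exempt, as are pairs
    within one unit; glycans carry their host segment's id."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = model.element != "H"
    ids = segment_ids[heavy]
    xyz = model.xyz[heavy]
    tree = cKDTree(xyz)
    for a, b in tree.query_pairs(r=cutoff):
        if ids[a] >= 0 and ids[b] >= 0 and ids[a] != ids[b]:
            return False
    return True


# ---------------------------------------------------------------------------
# Search


class SearchAborted(RuntimeError):
    pass


def run_search(start: StructureModel, linkers: LinkerSet,
               target: ScatteringCurve, n_trials: int, seed: int,
               domains: DomainMap, config: SearchConfig | None = None,
               start_label: str = "start") -> SearchResult:
    """Accumulate ``n_trials`` accepted (clash-free) trial conformations.

    Per-trial random streams are derived from the master seed by counter, so
    any trial is reproducible in isolation.  Aborts when the acceptance rate
    over the configured proposal window falls below the floor.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = config or SearchConfig()
    linkers.validate_against(domains)
    seg_ids = assign_segment_ids(start, domains)
    target_rg = guinier_fit(target).rg
    max_props = cfg.max_proposals or max(50 * n_trials, cfg.floor_window)
    noise_r = 0.0
    if target.sigma is not None:
        lo, hi = cfg.q_range if cfg.q_range else (target.q[0], target.q[-1])
        m = (target.q >= lo) & (target.q <= hi)
        # E|eps| = sigma sqrt(2/pi) for Gaussian noise
        noise_r = float(100.0 * np.sqrt(2.0 / np.pi)
                        * target.sigma[m].sum() / np.abs(target.i[m]).sum())

    rows = []
    best_heap: list[tuple] = []   # max-heap by (-R, ...) of size n_best
    n_acc = 0
    prop = 0
    window_acc: list[bool] = []
    while n_acc < n_trials and prop < max_props:
        trial_rng = np.random.default_rng([seed, prop])
        trial = perturb_linkers(start, linkers, step=cfg.step, seed=trial_rng,
                                mode=cfg.mode)
        prop += 1
        ok = clash_check(trial, seg_ids, cutoff=cfg.clash_cutoff)
        window_acc.append(ok)
        if len(window_acc) > cfg.floor_window:
            window_acc.pop(0)
        if not ok:
            rows.append({"trial": prop - 1, "rg": np.nan,
                         "r_factor": np.nan, "accepted": False})
            if (len(window_acc) == cfg.floor_window
                    and np.mean(window_acc) < cfg.acceptance_floor):
                raise SearchAborted(
                    f"acceptance rate {np.mean(window_acc):.3f} below floor "
                    f"{cfg.acceptance_floor} over {cfg.floor_window} proposals "
                    f"({n_acc} accepted of {prop})"
                )
            continue
        spheres = build_sphere_model(trial, cube_side=cfg.cube_side,
                                     hydrate=cfg.hydrate,
                                     dry_volume=cfg.dry_volume, mass=cfg.mass)
        curve = debye_curve(spheres, target.q)
        score = r_factor(target, curve, q_range=cfg.q_range)
        rg = spheres.radius_of_gyration()
        row = {"trial": prop - 1, "rg": rg, "r_factor": score.r_factor,
               "accepted": True}
        if cfg.geometry_hook is not None:
            row.update(cfg.geometry_hook(trial))
        rows.append(row)
        tc = TrialConformation(index=prop - 1, xyz=trial.xyz.copy(),
                               varied=perturbation_record(start, trial, linkers),
                               rg=rg, score=score)
        key = (-score.r_factor, -abs(rg - target_rg), -(prop - 1))
        if len(best_heap) < max(cfg.n_keep, cfg.n_best):
            heapq.heappush(best_heap, (key, tc))
        else:
            heapq.heappushpop(best_heap, (key, tc))
        n_acc += 1
    if n_acc < n_trials:
        raise SearchAborted(
            f"only {n_acc}/{n_trials} accepted within {max_props} proposals"
        )
    best = [tc for _, tc in sorted(best_heap, key=lambda kv: tuple(-x for x in kv[0]))]
    table = pd.DataFrame(rows)
    return SearchResult(table=table, best=best, seed=seed, n_proposed=prop,
                        n_accepted=n_acc, start_label=start_label,
                        target_rg=target_rg, noise_r_level=noise_r)


def select_best(result: SearchResult, n: int = 10,
                tie_epsilon: float = 0.0) -> list[TrialConformation]:
    """The n lowest-R-factor accepted trials.

    Ties are broken by smaller |R_g(model) - R_g(target fit)|, then by trial
    index.  ``tie_epsilon`` widens "tie" to R factors within that many
    percentage points of the minimum: trials inside the band are ranked by
    R_g agreement first, folding the measured overall size into selection
    exactly where the R factor alone cannot discriminate.  Pass
    ``result.noise_r_level`` to use the target's own noise floor as the band.
    Returns all retained trials, with a warning, if fewer than n exist.
    """
    import warnings

    pool = sorted(
        result.best,
        key=lambda t: (t.score.r_factor,
                       abs(t.rg - result.target_rg), t.index),
    )
    if not pool:
        raise ValueError("empty search result")
    if tie_epsilon > 0:
        rmin = pool[0].score.r_factor
        tied = [t for t in pool if t.score.r_factor <= rmin + tie_epsilon]
        rest = [t for t in pool if t.score.r_factor > rmin + tie_epsilon]
        tied.sort(key=lambda t: (abs(t.rg - result.target_rg),
                                 t.score.r_factor, t.index))
        pool = tied + rest
    if n > len(pool):
        warnings.warn(f"requested {n} best models, only {len(pool)} retained")
        return pool
    return pool[:n]


def conformation_model(start: StructureModel, trial: TrialConformation
                       ) -> StructureModel:
    """Materialize a trial's coordinates as a StructureModel."""
    out = start.copy()
    out.xyz = trial.xyz.copy()
    return out
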
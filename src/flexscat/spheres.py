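"""Cube-grid sphere models for scattering-curve simulation.

Atoms are binned onto a cubic grid; occupied cubes become equal spheres
whose individual volume equals the cube volume, so that the model's total
volume can be matched to the composition-derived dry volume of the
glycoprotein.  A hydrated model appends surface spheres until the total
volume equals the dry volume plus 0.3 g bound water per g glycoprotein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as k
from .structure import StructureModel


class VolumeMatchError(RuntimeError):
    pass


@dataclass
class SphereModel:
    centers: np.ndarray      # (m, 3) nm
    radius: float            # common sphere radius, nm
    hydrated: bool
    dry_volume: float        # target dry volume, nm^3
    total_volume: float      # realized model volume, nm^3
    n_dry: int               # spheres representing dry material

    @property
    def n_spheres(self) -> int:
        return len(self.centers)

    def radius_of_gyration(self) -> float:
        """R_g including the single-sphere parallel-axis term, nm."""
        c = self.centers.mean(axis=0)
        d2 = np.sum((self.centers - c) ** 2, axis=1)
        return float(np.sqrt(d2.mean() + 0.6 * self.radius**2))


def _grid_bins(xyz: np.ndarray, cube_side: float):
    origin = xyz.min(axis=0) - 0.5 * cube_side
    idx = np.floor((xyz - origin) / cube_side).astype(np.int64)
    return origin, idx


_NEIGH = [(dx, dy, dz)
          for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
          if (dx, dy, dz) != (0, 0, 0)]


def _grow_shell(filled: set, n_extra: int) -> list:
    """Add ``n_extra`` empty cubes adjacent to the filled set, preferring the
    most-buried surface positions; ties resolve by grid index so growth is
    deterministic.  Grows shell by shell if one layer is not enough."""
    out: list[tuple] = []
    shell_src = set(filled)
    filled = set(filled)
    while len(out) < n_extra and shell_src:
        cand: dict[tuple, int] = {}
        for c in shell_src:
            for d in _NEIGH:
                t = (c[0] + d[0], c[1] + d[1], c[2] + d[2])
                if t not in filled:
                    cand[t] = cand.get(t, 0) + 1
        if not cand:
            break
        ordered = sorted(cand.items(), key=lambda it: (-it[1], it[0]))
        take = [t for t, _ in ordered[: n_extra - len(out)]]
        out.extend(take)
        filled.update(take)
        shell_src = set(take)
    return out


def build_sphere_model(model: StructureModel, cube_side: float = 0.55,
                       atom_cutoff: int | None = None, hydrate: bool = False,
                       dry_volume: float | None = None,
                       mass: float | None = None) -> SphereModel:
    """Coarse-grain atoms into an equal-sphere model on a cubic grid.

    With ``atom_cutoff=None`` (default) the occupancy threshold is auto-tuned:
    an integer search over cutoffs 1..8 picks the one minimizing the dry-volume
    error, and the cube set is then refined by atom-count rank (densest cubes
    first, ties by grid index) to the cube count matching the target volume.
    An explicit cutoff disables refinement and may fail the 1% volume match.
    """
    if not (0.2 < cube_side < 1.2):
        raise ValueError("cube_side outside (0.2, 1.2) nm")
    if model.n_atoms == 0:
        raise ValueError("empty model")
    v_dry = model.dry_volume() if dry_volume is None else float(dry_volume)
    cube_vol = cube_side**3
    radius = (3.0 * cube_vol / (4.0 * np.pi)) ** (1.0 / 3.0)

    origin, idx = _grid_bins(model.xyz, cube_side)
    cubes, counts = np.unique(idx, axis=0, return_counts=True)
    # lexicographic cube order for deterministic tie-breaks
    order = np.lexsort((cubes[:, 2], cubes[:, 1], cubes[:, 0]))
    cubes, counts = cubes[order], counts[order]

    if atom_cutoff is not None:
        keep = counts >= atom_cutoff
    else:
        best = None
        for cut in range(1, 9):
            err = abs(int((counts >= cut).sum()) * cube_vol - v_dry)
            if best is None or err < best[0]:
                best = (err, cut)
        n_target = max(1, int(round(v_dry / cube_vol)))
        # densest cubes first; stable sort keeps grid-index order on ties
        rank = np.argsort(-counts, kind="stable")
        keep = np.zeros(len(cubes), dtype=bool)
        keep[rank[:n_target]] = True
    sel = cubes[keep]
    if len(sel) == 0:
        raise VolumeMatchError("no cube reaches the atom cutoff")
    if atom_cutoff is None and n_target > len(sel):
        # sparse atom sets (pseudo-atom models) underfill the interior; top
        # up with adjacent cubes so the dry volume still matches composition
        extra = _grow_shell({tuple(c) for c in sel}, n_target - len(sel))
        if extra:
            sel = np.vstack([sel, np.array(extra, dtype=np.int64)])
    vol = len(sel) * cube_vol
    if atom_cutoff is None and abs(vol - v_dry) > 0.01 * v_dry \
            and v_dry > 50 * cube_vol:
        raise VolumeMatchError(
            f"dry volume {vol:.2f} nm^3 vs target {v_dry:.2f} nm^3 (>1% off)"
        )
    centers = origin + (sel + 0.5) * cube_side
    n_dry = len(sel)
    total = vol

    if hydrate:
        m = model.molecular_mass() if mass is None else float(mass)
        v_hyd = v_dry + k.HYDRATION_G_PER_G * m * k.NM3_PER_DA_AT_UNIT_DENSITY \
            / k.WATER_DENSITY_HYDRATION
        n_extra = int(round((v_hyd - vol) / cube_vol))
        extra = _grow_shell({tuple(c) for c in sel}, n_extra)
        if extra:
            extra_centers = origin + (np.array(extra) + 0.5) * cube_side
            centers = np.vstack([centers, extra_centers])
        total = len(centers) * cube_vol

    return SphereModel(centers=centers, radius=radius, hydrated=hydrate,
                       dry_volume=v_dry, total_volume=total, n_dry=n_dry)
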
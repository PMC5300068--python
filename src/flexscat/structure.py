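"""Coordinate models, domain/linker annotation and glycan stubs.

The central container is :class:`StructureModel`, a flat array-of-atoms
representation (coordinates in nm) read from and written to standard PDB
files via gemmi.  Rigid domains and flexible linkers are declared beside it
with :class:`DomainMap` and :class:`LinkerSet`; simplified extended N-glycans
are appended as pseudo-residue bead chains with :func:`attach_glycans`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import constants as k

NM_PER_ANGSTROM = 0.1


class PDBParseError(ValueError):
    pass


@dataclass
class StructureModel:
    """Atoms with coordinates (nm), chain/residue bookkeeping and optional
    per-atom mass/volume overrides (used by pseudo-atom models)."""

    element: np.ndarray          # (n,) unicode
    name: np.ndarray             # (n,) atom names
    resname: np.ndarray          # (n,)
    resseq: np.ndarray           # (n,) int residue numbers, verbatim
    icode: np.ndarray            # (n,) insertion codes, verbatim
    chain: np.ndarray            # (n,)
    het: np.ndarray              # (n,) bool, HETATM records
    xyz: np.ndarray              # (n, 3) float, nm
    glycan: np.ndarray = None    # (n,) bool, appended glycan pseudo-atoms
    anchor_resseq: np.ndarray = None  # (n,) int; glycan host residue, else -1
    atom_mass: np.ndarray = None     # (n,) Da; NaN -> use composition tables
    atom_volume: np.ndarray = None   # (n,) nm^3; NaN -> use composition tables

    def __post_init__(self):
        n = len(self.xyz)
        if self.glycan is None:
            self.glycan = np.zeros(n, dtype=bool)
        if self.anchor_resseq is None:
            self.anchor_resseq = np.full(n, -1, dtype=int)
        if self.atom_mass is None:
            self.atom_mass = np.full(n, np.nan)
        if self.atom_volume is None:
            self.atom_volume = np.full(n, np.nan)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.xyz)

    def copy(self) -> "StructureModel":
        return StructureModel(**{
            f.name: getattr(self, f.name).copy()
            for f in dataclasses.fields(self)
        })

    def chains(self) -> list[str]:
        seen = []
        for c in self.chain:
            if c not in seen:
                seen.append(c)
        return seen

    def mask(self, chain=None, resseq=None, res_range=None, protein_only=False):
        """Boolean mask over atoms by chain, residue number or inclusive range."""
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            m &= self.chain == chain
        if resseq is not None:
            m &= self.resseq == resseq
        if res_range is not None:
            lo, hi = res_range
            m &= (self.resseq >= lo) & (self.resseq <= hi)
        if protein_only:
            m &= ~self.het & ~self.glycan
        return m

    def residue_index(self) -> np.ndarray:
        """Integer id, contiguous per residue in file order."""
        keys = list(zip(self.chain, self.resseq, self.icode))
        ids = np.empty(self.n_atoms, dtype=int)
        last, cur = None, -1
        for i, key in enumerate(keys):
            if key != last:
                cur += 1
                last = key
            ids[i] = cur
        return ids

    def sequences(self) -> dict[str, str]:
        """One-letter sequence per chain (standard residues only)."""
        out: dict[str, list[str]] = {}
        rid = self.residue_index()
        for i in np.flatnonzero(np.r_[True, np.diff(rid) != 0]):
            rn = self.resname[i]
            if rn in k.THREE_TO_ONE and not self.het[i] and not self.glycan[i]:
                out.setdefault(self.chain[i], []).append(k.THREE_TO_ONE[rn])
        return {c: "".join(s) for c, s in out.items()}

    def atom_masses(self) -> np.ndarray:
        m = self.atom_mass.copy()
        missing = ~np.isfinite(m)
        for i in np.flatnonzero(missing):
            m[i] = k.ELEMENT_MASS.get(self.element[i], 12.011)
        return m

    def centroid(self, mask=None) -> np.ndarray:
        x = self.xyz if mask is None else self.xyz[mask]
        return x.mean(axis=0)

    def radius_of_gyration(self) -> float:
        """Mass-weighted R_g in nm."""
        m = self.atom_masses()
        c = np.average(self.xyz, axis=0, weights=m)
        d2 = np.sum((self.xyz - c) ** 2, axis=1)
        return float(np.sqrt(np.average(d2, weights=m)))

    # -- composition bookkeeping ------------------------------------------

    def dry_volume(self) -> float:
        """Composition-derived dry volume in nm^3.

        Standard residues use the packaged residue-volume table (one value per
        residue); glycan pseudo-atoms and other atoms with a volume override
        contribute their per-atom values; retained ions use the ion table.
        """
        total = 0.0
        rid = self.residue_index()
        override = np.isfinite(self.atom_volume)
        total += float(self.atom_volume[override].sum())
        starts = np.flatnonzero(np.r_[True, np.diff(rid) != 0])
        for i in starts:
            if override[i]:
                continue
            rn = self.resname[i]
            if rn in k.RESIDUE_VOLUME:
                total += k.RESIDUE_VOLUME[rn]
            elif rn.strip() in k.ION_VOLUME:
                total += k.ION_VOLUME[rn.strip()]
            elif rn == "HOH":
                continue
            else:
                raise KeyError(
                    f"no volume for residue {rn!r}; supply atom_volume overrides"
                )
        return total

    def molecular_mass(self) -> float:
        """Composition-derived mass in Da (chains + overrides + ions)."""
        total = 0.0
        rid = self.residue_index()
        override = np.isfinite(self.atom_mass)
        total += float(self.atom_mass[override].sum())
        starts = np.flatnonzero(np.r_[True, np.diff(rid) != 0])
        chains_seen = set()
        for i in starts:
            if override[i]:
                continue
            rn = self.resname[i]
            if rn in k.RESIDUE_MASS:
                total += k.RESIDUE_MASS[rn]
                chains_seen.add(self.chain[i])
            elif rn.strip() in k.ION_MASS:
                total += k.ION_MASS[rn.strip()]
            elif rn == "HOH":
                continue
            else:
                raise KeyError(f"no mass for residue {rn!r}")
        total += k.WATER_MASS * len(chains_seen)
        return total


# ---------------------------------------------------------------------------
# Domain / linker annotation


@dataclass(frozen=True)
class Segment:
    name: str
    chain: str
    start: int
    end: int  # inclusive
    rigid: bool = True

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"segment {self.name}: end < start")


@dataclass
class DomainMap:
    """Named chain segments with rigid flags; ranges are inclusive and taken
    verbatim from file numbering."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self):
        by_chain: dict[str, list[Segment]] = {}
        for s in self.segments:
            by_chain.setdefault(s.chain, []).append(s)
        for chain, segs in by_chain.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"overlapping segments {a.name}/{b.name} in chain {chain}"
                    )

    def get(self, name: str, chain: str | None = None) -> list[Segment]:
        out = [s for s in self.segments
               if s.name == name and (chain is None or s.chain == chain)]
        if not out:
            raise KeyError(f"no segment {name!r} (chain {chain!r})")
        return out

    def rigid_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.rigid]


@dataclass(frozen=True)
class Linker:
    chain: str
    start: int
    end: int  # inclusive

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("empty linker range")


@dataclass
class LinkerSet:
    linkers: list[Linker] = field(default_factory=list)

    def validate_against(self, domains: DomainMap):
        for ln in self.linkers:
            for seg in domains.rigid_segments():
                if seg.chain == ln.chain and not (
                    ln.end < seg.start or ln.start > seg.end
                ):
                    raise ValueError(
                        f"linker {ln} overlaps rigid segment {seg.name}"
                    )


def assign_segment_ids(model: StructureModel, domains: DomainMap) -> np.ndarray:
    """Per-atom rigid-unit id; -1 for linker/unassigned atoms.

    Glycan pseudo-atoms inherit the id of the rigid segment nearest to their
    attachment (they ride rigidly with it), so that glycan-versus-other-segment
    contacts are checked but a glycan never clashes with its own host.
    """
    ids = np.full(model.n_atoms, -1, dtype=int)
    rigid = domains.rigid_segments()
    # contiguous rigid segments of one chain (no linker between them) move
    # as one body and form a single clash unit, e.g. the CUB1-EGF core
    rigid = sorted(rigid, key=lambda s: (s.chain, s.start))
    unit_of: list[int] = []
    next_unit = 0
    for i, seg in enumerate(rigid):
        if i > 0 and seg.chain == rigid[i - 1].chain \
                and seg.start == rigid[i - 1].end + 1:
            unit_of.append(unit_of[-1])
        else:
            unit_of.append(next_unit)
            next_unit += 1
    for j, seg in enumerate(rigid):
        m = model.mask(chain=seg.chain, res_range=(seg.start, seg.end))
        ids[m & ~model.glycan] = unit_of[j]
        gm = model.glycan & (model.chain == seg.chain) & \
            (model.anchor_resseq >= seg.start) & (model.anchor_resseq <= seg.end)
        ids[gm] = unit_of[j]
    gly = np.flatnonzero(model.glycan & (ids < 0))
    if len(gly):
        assigned = np.flatnonzero(ids >= 0)
        if len(assigned):
            from scipy.spatial import cKDTree

            tree = cKDTree(model.xyz[assigned])
            _, nearest = tree.query(model.xyz[gly])
            ids[gly] = ids[assigned[nearest]]
    return ids


# ---------------------------------------------------------------------------
# PDB input / output


def _model_from_gemmi(st: gemmi.Structure) -> StructureModel:
    st.setup_entities()
    if len(st) == 0:
        raise PDBParseError("no models in file")
    model = st[0]
    rows = []
    seen = set()
    for chain in model:
        for res in chain:
            # keep the highest-occupancy altloc conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                occ = atom.occ if atom.occ > 0 else 1.0
                prev = best.get(atom.name)
                if prev is None or occ > (prev.occ if prev.occ > 0 else 1.0):
                    best[atom.name] = atom
            for atom in best.values():
                if res.name == "HOH":
                    continue
                key = (chain.name, res.seqid.num, res.seqid.icode, atom.name)
                if key in seen:
                    raise PDBParseError(f"duplicate atom identifier {key}")
                seen.add(key)
                rows.append((
                    atom.element.name.upper(),
                    atom.name,
                    res.name,
                    res.seqid.num,
                    (res.seqid.icode or " ").strip() or " ",
                    chain.name,
                    res.het_flag == "H",
                    atom.pos.x * NM_PER_ANGSTROM,
                    atom.pos.y * NM_PER_ANGSTROM,
                    atom.pos.z * NM_PER_ANGSTROM,
                ))
    if not rows:
        raise PDBParseError("zero atoms")
    cols = list(zip(*rows))
    return StructureModel(
        element=np.array(cols[0]),
        name=np.array(cols[1]),
        resname=np.array(cols[2]),
        resseq=np.array(cols[3], dtype=int),
        icode=np.array(cols[4]),
        chain=np.array(cols[5]),
        het=np.array(cols[6], dtype=bool),
        xyz=np.array(cols[7:10], dtype=float).T.copy(),
    )


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB-format file into a StructureModel (coordinates in nm).

    Waters are dropped; other heteroatoms (bound Ca2+ etc.) are retained.
    Altloc conflicts resolve to the highest-occupancy conformer.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as e:
        raise PDBParseError(f"cannot parse {path}: {e}") from e
    return _model_from_gemmi(st)


def read_structure_text(text: str) -> StructureModel:
    """Parse PDB-format text held in memory."""
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as e:
        raise PDBParseError(f"cannot parse PDB text: {e}") from e
    return _model_from_gemmi(st)


def write_structure(model: StructureModel, path: str | Path):
    """Write a StructureModel as a PDB file (nm converted back to Angstrom)."""
    st = gemmi.Structure()
    st.add_model(gemmi.Model("1"))
    gm = st[0]
    for c in model.chains():
        gm.add_chain(gemmi.Chain(c))
    chain_lookup = {c.name: c for c in gm}
    rid = model.residue_index()
    last = -1
    res = None
    for i in range(model.n_atoms):
        if rid[i] != last:
            res = gemmi.Residue()
            res.name = str(model.resname[i])
            res.seqid = gemmi.SeqId(int(model.resseq[i]),
                                    str(model.icode[i])[0] if str(model.icode[i]).strip() else " ")
            res.het_flag = "H" if model.het[i] else "A"
            chain_lookup[str(model.chain[i])].add_residue(res)
            res = chain_lookup[str(model.chain[i])][-1]
            last = rid[i]
        atom = gemmi.Atom()
        atom.name = str(model.name[i])
        atom.element = gemmi.Element(str(model.element[i]).capitalize())
        atom.occ = 1.0
        atom.pos = gemmi.Position(*(model.xyz[i] / NM_PER_ANGSTROM))
        res.add_atom(atom)
    st.setup_entities()
    Path(path).write_text(st.make_pdb_string())


# ---------------------------------------------------------------------------
# Glycan stubs


@dataclass(frozen=True)
class GlycanStub:
    """A simplified extended N-glycan: a linear chain of sugar beads grown
    outward from an attachment Asn."""

    chain: str
    resseq: int
    n_units: int = 11
    unit_mass: float = k.SUGAR_UNIT_MASS
    unit_volume: float = k.SUGAR_UNIT_VOLUME
    direction: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.n_units <= 0 or self.unit_mass <= 0 or self.unit_volume <= 0:
            raise ValueError("glycan stub parameters must be positive")

    @property
    def bead_radius(self) -> float:
        return float((3.0 * self.unit_volume / (4.0 * np.pi)) ** (1.0 / 3.0))


class GlycanPlacementError(RuntimeError):
    pass


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * angle).as_matrix()


def attach_glycans(model: StructureModel, stubs: list[GlycanStub],
                   seed: int = 0, clash_cutoff: float = 0.25,
                   max_retries: int = 100) -> StructureModel:
    """Append glycan bead chains along the outward normal of each site.

    Pre-existing atom coordinates are never modified.  Each bead chain is
    grown along the direction from the protein centroid through the
    attachment-residue centroid; if any bead comes closer than
    ``bead_radius + clash_cutoff`` (center-to-surface rule) to a protein atom,
    the direction is re-tilted at random, up to ``max_retries`` times.
    """
    if not stubs:
        return model.copy()
    rng = np.random.default_rng(seed)
    out = model.copy()
    protein_xyz = model.xyz[~model.glycan]
    center = model.centroid()
    new_rows = []
    next_res = int(model.resseq.max()) + 1
    for stub in stubs:
        site = model.mask(chain=stub.chain, resseq=stub.resseq)
        site &= ~model.glycan
        if not site.any():
            raise GlycanPlacementError(
                f"attachment residue {stub.chain}:{stub.resseq} missing"
            )
        base = model.centroid(site)
        if stub.direction is not None:
            d0 = np.asarray(stub.direction, dtype=float)
        else:
            d0 = base - center
        if np.linalg.norm(d0) < 1e-9:
            d0 = np.array([0.0, 0.0, 1.0])
        d0 = d0 / np.linalg.norm(d0)
        spacing = 2.0 * stub.bead_radius
        placed = None
        for attempt in range(max_retries + 1):
            if attempt == 0:
                d = d0
            else:
                tilt = rng.normal(size=3)
                tilt -= tilt.dot(d0) * d0
                nt = np.linalg.norm(tilt)
                if nt < 1e-12:
                    continue
                ang = rng.uniform(0, np.deg2rad(60.0))
                d = _rotation_about(np.cross(d0, tilt / nt), ang) @ d0
            beads = base + spacing * np.arange(1, stub.n_units + 1)[:, None] * d
            from scipy.spatial import cKDTree

            tree = cKDTree(protein_xyz)
            dmin = tree.query(beads)[0]
            # exempt the first bead's inevitable contact with its own Asn
            limit = stub.bead_radius + clash_cutoff
            ok = np.all(dmin[1:] >= limit) and dmin[0] >= 0.5 * limit
            if ok:
                placed = beads
                break
        if placed is None:
            raise GlycanPlacementError(
                f"no clash-free glycan placement at {stub.chain}:{stub.resseq}"
            )
        for b in placed:
            new_rows.append((stub, b, next_res))
            next_res += 1
    n_new = len(new_rows)
    app = {
        "element": np.array(["C"] * n_new),
        "name": np.array(["C1"] * n_new),
        "resname": np.array([k.GLYCAN_RESNAME] * n_new),
        "resseq": np.array([r[2] for r in new_rows], dtype=int),
        "icode": np.array([" "] * n_new),
        "chain": np.array([r[0].chain for r in new_rows]),
        "het": np.ones(n_new, dtype=bool),
        "xyz": np.array([r[1] for r in new_rows]),
        "glycan": np.ones(n_new, dtype=bool),
        "anchor_resseq": np.array([r[0].resseq for r in new_rows], dtype=int),
        "atom_mass": np.array([r[0].unit_mass for r in new_rows]),
        "atom_volume": np.array([r[0].unit_volume for r in new_rows]),
    }
    for f in dataclasses.fields(out):
        setattr(out, f.name,
                np.concatenate([getattr(out, f.name), app[f.name]]))
    return out
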
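"""Structure-derived analyses of deposited MASP coordinate sets.

These routines reproduce, from user-supplied PDB files, the numbers that
characterize the crystallographic MASP CUB1-EGF-CUB2 ("3D") dimers: the
Guinier R_g of the hydrated sphere model, the Kirkwood bead-model s20,w,
the dimer-interface buried surface area, trimmed-Calpha overlay RMSDs, and
the CUB2 centroid separation / bend angle of the two-armed dimer.

Coordinate files are not shipped with the package (they are large and
redistributable from the PDB); point ``reference_report`` at a directory
holding them, e.g. 5ckq.pdb (rat MASP-1 3D), 5ckn.pdb / 5cis.pdb /
5ckm.pdb (rat MASP-2 3D), 3dem.pdb (human MASP-1 3D) and 1nt0.pdb
(earlier rat MASP-2 3D).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import bend_parameters, buried_surface_area, superpose
from .hydro import bead_model_from_atoms, composition_properties, sedimentation_coefficient
from .scattering import debye_curve, guinier_fit
from .spheres import build_sphere_model
from .structure import DomainMap, Segment, StructureModel, read_structure

# Approximate mature-chain domain boundaries of the rat MASP 3D fragments
# (CUB1 / EGF-like / CUB2); ranges are applied per chain and clipped to the
# residues present in the file.
MASP_3D_BOUNDARIES = {"CUB1": (1, 121), "EGF": (122, 166), "CUB2": (167, 300)}


def masp_domain_map(model: StructureModel,
                    boundaries: dict | None = None) -> DomainMap:
    """DomainMap for a two-chain MASP 3D dimer from residue-range boundaries,
    clipped to the residues actually present in each chain."""
    boundaries = boundaries or MASP_3D_BOUNDARIES
    segs = []
    for chain in model.chains():
        resseq = model.resseq[(model.chain == chain) & ~model.het]
        if len(resseq) == 0:
            continue
        lo, hi = int(resseq.min()), int(resseq.max())
        for name, (a, b) in boundaries.items():
            a2, b2 = max(a, lo), min(b, hi)
            if a2 <= b2:
                segs.append(Segment(name, chain, a2, b2, True))
    return DomainMap(segs)


def dimer_chains(model: StructureModel) -> tuple[str, str]:
    counts = {c: int(np.sum((model.chain == c) & ~model.het))
              for c in model.chains()}
    top = sorted(counts, key=counts.get, reverse=True)[:2]
    if len(top) < 2:
        raise ValueError("file does not contain a two-chain dimer")
    return tuple(sorted(top))


def analyze_masp_dimer(path: str | Path,
                       q_grid: np.ndarray | None = None) -> dict:
    """Sphere-model R_g, predicted s20,w, interface BSA and bend geometry of
    one MASP 3D dimer coordinate file."""
    model = read_structure(path)
    chains = dimer_chains(model)
    q = np.linspace(0.05, 2.0, 120) if q_grid is None else q_grid
    spheres = build_sphere_model(model, hydrate=True)
    curve = debye_curve(spheres, q)
    rg = guinier_fit(curve).rg
    props = composition_properties(model.sequences())
    hydro = sedimentation_coefficient(bead_model_from_atoms(model), props)
    ga = np.isin(model.chain, [chains[0]])
    gb = np.isin(model.chain, [chains[1]])
    bsa = buried_surface_area(model, ga, gb)
    domains = masp_domain_map(model)
    geom = bend_parameters(model, domains, end_domain="CUB2",
                           core_domains=("CUB1", "EGF"), chains=chains)
    return {
        "guinier_rg_nm": rg,
        "s20w_S": hydro.s20w,
        "mass_kda": props.mass_kda,
        "bsa_per_molecule_a2": bsa["per_molecule_a2"],
        "stable_dimer": bsa["stable_dimer"],
        "cub2_separation_nm": geom.separation_nm,
        "theta_deg": geom.theta_deg,
    }


def overlay_rmsd(path_a: str | Path, path_b: str | Path,
                 trim_sigma: float = 2.0) -> dict:
    """Trimmed-Calpha overlay of the first chains of two coordinate files."""
    a = read_structure(path_a)
    b = read_structure(path_b)

    def first_chain(m):
        import dataclasses

        chain = dimer_chains(m)[0] if len(m.chains()) > 1 else m.chains()[0]
        keep = m.mask(chain=chain)
        out = {f.name: getattr(m, f.name)[keep]
               for f in dataclasses.fields(m)}
        out["chain"] = np.array(["A"] * int(keep.sum()))
        return StructureModel(**out)

    res = superpose(first_chain(a), first_chain(b), trim_sigma=trim_sigma)
    return {"rmsd_a": res.rmsd_a, "n_retained": res.n_retained,
            "n_rejected": len(res.rejected)}


def reference_report(directory: str | Path) -> dict:
    """All structure-derived quantities computable from a directory of the
    deposited MASP coordinate files (lower-case names, .pdb extension)."""
    directory = Path(directory)

    def need(name):
        p = directory / name
        if not p.exists():
            raise FileNotFoundError(
                f"{p}: deposited coordinate files must be supplied locally")
        return p

    report = {}
    for code in ("5ckq", "5ckn", "5cis", "5ckm"):
        report[code] = analyze_masp_dimer(need(f"{code}.pdb"))
    report["rmsd_masp1_rat_vs_human"] = overlay_rmsd(need("5ckq.pdb"),
                                                     need("3dem.pdb"))
    masp2 = ["5ckn", "5cis", "5ckm"]
    for i in range(len(masp2)):
        for j in range(i + 1, len(masp2)):
            report[f"rmsd_{masp2[i]}_vs_{masp2[j]}"] = overlay_rmsd(
                need(f"{masp2[i]}.pdb"), need(f"{masp2[j]}.pdb"))
        report[f"rmsd_{masp2[i]}_vs_1nt0"] = overlay_rmsd(
            need(f"{masp2[i]}.pdb"), need("1nt0.pdb"))
    return report
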
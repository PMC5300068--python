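"""Run configuration: domains, linkers and glycans declared in YAML.

Example::

    domains:
      - {name: CUB1, chain: A, start: 1, end: 121}
      - {name: EGF,  chain: A, start: 122, end: 166}
      - {name: CUB2, chain: A, start: 176, end: 283, rigid: true}
    linkers:
      - {chain: A, start: 167, end: 175}
    glycans:
      - {chain: A, residue: 105, units: 11}
    search:
      n_trials: 2000
      cube_side: 0.55
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .sampling import SearchConfig
from .structure import DomainMap, GlycanStub, Linker, LinkerSet, Segment


@dataclass
class RunConfig:
    domains: DomainMap
    linkers: LinkerSet
    glycans: list[GlycanStub]
    search: SearchConfig
    n_trials: int = 2000
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    segs = [
        Segment(d["name"], str(d["chain"]), int(d["start"]), int(d["end"]),
                bool(d.get("rigid", True)))
        for d in raw.get("domains", [])
    ]
    links = [
        Linker(str(d["chain"]), int(d["start"]), int(d["end"]))
        for d in raw.get("linkers", [])
    ]
    stubs = []
    for d in raw.get("glycans", []):
        kwargs = {"chain": str(d["chain"]), "resseq": int(d["residue"])}
        if "units" in d:
            kwargs["n_units"] = int(d["units"])
        if "unit_mass" in d:
            kwargs["unit_mass"] = float(d["unit_mass"])
        if "unit_volume" in d:
            kwargs["unit_volume"] = float(d["unit_volume"])
        stubs.append(GlycanStub(**kwargs))
    sraw = dict(raw.get("search", {}))
    n_trials = int(sraw.pop("n_trials", 2000))
    seed = int(sraw.pop("seed", 0))
    valid = {f.name for f in fields(SearchConfig)}
    unknown = set(sraw) - valid
    if unknown:
        raise KeyError(f"unknown search option(s): {sorted(unknown)}")
    cfg = SearchConfig(**sraw)
    dm = DomainMap(segs)
    ls = LinkerSet(links)
    ls.validate_against(dm)
    return RunConfig(domains=dm, linkers=ls, glycans=stubs, search=cfg,
                     n_trials=n_trials, seed=seed)
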
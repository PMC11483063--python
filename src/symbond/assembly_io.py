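"""Structure and table I/O, run configuration, and provenance records.

Coordinates are Å in right-handed axes with no implicit origin shifts.
PDB output is limited to assemblies whose chain identifiers fit the
single-character PDB field; anything larger (e.g. 120-chain icosahedral
assemblies) is written as mmCIF. Every artifact gets a sidecar
provenance record (config hash + seed) so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as cif_get_structure, set_structure as cif_set_structure

from .geometry import Chain

__all__ = [
    "read_structure",
    "write_structure",
    "RunConfig",
    "read_config",
    "write_provenance",
    "StructureFormatError",
]

#: PDB format exhausts its chain-ID alphabet here
PDB_MAX_CHAINS = 62


class StructureFormatError(ValueError):
    pass


def _chains_of(obj) -> list[Chain]:
    if isinstance(obj, Chain):
        return [obj]
    if hasattr(obj, "all_chains"):
        return obj.all_chains()
    if hasattr(obj, "chains"):
        return list(obj.chains)
    return list(obj)


def _to_atom_array(chains: list[Chain]) -> struc.AtomArray:
    n = sum(len(c) for c in chains)
    arr = struc.AtomArray(n)
    arr.add_annotation("b_factor", float)
    pos = 0
    for c in chains:
        m = len(c)
        sl = slice(pos, pos + m)
        arr.coord[sl] = c.coords
        arr.chain_id[sl] = c.chain_id
        arr.res_id[sl] = c.res_ids
        arr.res_name[sl] = "ALA"
        arr.atom_name[sl] = c.atom_names
        arr.element[sl] = c.elements
        arr.b_factor[sl] = c.b_factors
        arr.hetero[sl] = False
        pos += m
    return arr


def _from_atom_array(arr: struc.AtomArray) -> list[Chain]:
    chains: list[Chain] = []
    b = arr.get_annotation("b_factor") if "b_factor" in arr.get_annotation_categories() else np.zeros(arr.array_length())
    for cid in np.unique(arr.chain_id):
        mask = arr.chain_id == cid
        chains.append(
            Chain(
                chain_id=str(cid),
                coords=arr.coord[mask],
                atom_names=arr.atom_name[mask],
                elements=arr.element[mask],
                res_ids=arr.res_id[mask],
                b_factors=np.asarray(b)[mask],
            )
        )
    chains.sort(key=lambda c: c.chain_id)
    return chains


def read_structure(path: str | Path) -> list[Chain]:
    """Read a PDB or mmCIF file (by extension) into chains."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix == ".pdb":
            arr = PDBFile.read(str(path)).get_structure(model=1, extra_fields=["b_factor"])
        elif suffix in (".cif", ".mmcif"):
            arr = cif_get_structure(CIFFile.read(str(path)), model=1, extra_fields=["b_factor"])
        else:
            raise StructureFormatError(f"unsupported structure extension {suffix!r}")
    except StructureFormatError:
        raise
    except Exception as e:
        raise StructureFormatError(f"cannot parse {path}: {e}") from e
    return _from_atom_array(arr)


def write_structure(obj, path: str | Path) -> Path:
    """Write chains / a block / an assembly to PDB or mmCIF.

    Assemblies exceeding the PDB chain-identifier alphabet (62 chains,
    or any multi-character chain id) must go to mmCIF; requesting .pdb
    for them is an error.
    """
    path = Path(path)
    chains = _chains_of(obj)
    if not chains:
        raise ValueError("nothing to write: no chains")
    ids = [c.chain_id for c in chains]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate chain identifiers")
    arr = _to_atom_array(chains)
    suffix = path.suffix.lower()
    needs_cif = len(chains) > PDB_MAX_CHAINS or any(len(i) > 1 for i in ids)
    if suffix == ".pdb":
        if needs_cif:
            raise StructureFormatError(
                f"{len(chains)} chains exceed PDB chain-ID capacity; write mmCIF (.cif) instead"
            )
        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    elif suffix in (".cif", ".mmcif"):
        f = CIFFile()
        cif_set_structure(f, arr)
        f.write(str(path))
    else:
        raise StructureFormatError(f"unsupported structure extension {path.suffix!r}")
    return path


# --- run configuration ----------------------------------------------

_CONFIG_DEFAULTS: dict[str, float | int | str] = {
    "architecture": "T33",
    "toy_ring_radius": 15.0,
    "toy_helix_length": 30,
    "clash_cutoff": 4.0,
    "tolerance": 0.1,
    "lever_arm": 10.0,
    "score_scale": 10.0,
    "plddt_min": 90.0,
    "ptm_min": 0.80,
    "rmsd_cut": 2.0,
    "met_max": 5,
    "sc_min": 0.6,
    "ddg_max": -20.0,
    "sasa_max": 1600.0,
    "clash_max": 2,
    "unsat_max": 2,
    "sap_max": 30.0,
    "saxs_n_pairs": 10_000_000,
    "saxs_dr": 1.0,
    "lattice_a": 200.0,
    "seed": 0,
    "out_dir": "out",
}


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; every threshold has a default so partial
    configs are valid, and the seed is recorded in all provenance."""

    values: dict

    def __getattr__(self, name):
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name)

    def hash(self) -> str:
        payload = json.dumps(self.values, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Flat ``key = value`` config file; '#' comments; unknown keys are
    errors (fail fast)."""
    values = dict(_CONFIG_DEFAULTS)
    if path is not None:
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}, line {lineno}: expected 'key = value'")
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in _CONFIG_DEFAULTS:
                raise ValueError(f"{path}, line {lineno}: unknown config key {key!r}")
            values[key] = _coerce(val, _CONFIG_DEFAULTS[key])
    for key, val in overrides.items():
        if key not in _CONFIG_DEFAULTS:
            raise ValueError(f"unknown config key {key!r}")
        values[key] = val
    return RunConfig(values=values)


def _coerce(text: str, default):
    if isinstance(default, int) and not isinstance(default, bool):
        try:
            return int(text)
        except ValueError:
            return float(text)
    if isinstance(default, float):
        return float(text)
    return text


def write_provenance(path: str | Path, config: RunConfig, **extra) -> Path:
    """Sidecar JSON: config hash, seed, and run parameters. No
    timestamps, so identical reruns are byte-identical."""
    path = Path(path)
    record = {
        "config_hash": config.hash(),
        "seed": config.values.get("seed"),
        "config": {k: v for k, v in sorted(config.values.items())},
    }
    record.update(extra)
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
    return path
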
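"""P3 2D layers and F432 3D crystals from placed blocks and cages.

Open (unbounded) architectures are generated as finite coordinate
patches — no periodic boundary — because electron-microscopy and SAXS
comparisons are made on finite crystallites. The module also provides
zone-axis projections and Bragg reflection positions (selection rules
only; no intensities).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .building_blocks import OligomerBlock
from .geometry import Chain, RigidTransform, chain_id_stream
from .placement_engine import ArchitectureError, AssemblyModel, place_on_axis
from .symmetry_core import build_point_group

__all__ = [
    "PlaneGroupLayer",
    "CrystalModel",
    "build_p3_layer",
    "build_f432_crystal",
    "zone_axis_projection",
    "bragg_positions",
    "local_tetrahedron_counts",
]


@dataclass(frozen=True)
class PlaneGroupLayer:
    """P3 hexagonal layer: equal-length lattice vectors at 120°, with
    threefold sites at (0,0), (1/3,2/3), (2/3,1/3) in fractional 2D
    coordinates. Two of the three sites carry C3 blocks; per-site
    placement is (z-offset, spin about the site's 3-fold)."""

    a: float
    n_cells: int
    sites: tuple[tuple[float, float], ...] = ((0.0, 0.0), (1 / 3, 2 / 3), (2 / 3, 1 / 3))
    occupancy: tuple[str | None, ...] = (None, None, None)
    z_offsets: tuple[float, ...] = (0.0, 0.0, 0.0)
    rotations: tuple[float, ...] = (0.0, 0.0, 0.0)
    plane_group: str = "P3"

    def lattice_vectors(self) -> np.ndarray:
        """Rows a1, a2 (Å, 3-vectors) at 120° in the xy-plane."""
        a1 = np.array([self.a, 0.0, 0.0])
        a2 = np.array([-0.5 * self.a, 0.5 * np.sqrt(3.0) * self.a, 0.0])
        return np.stack([a1, a2])


@dataclass(frozen=True)
class CrystalModel:
    """F432 cubic crystal: cages at FCC nodes, C3 linkers at
    (1/4,1/4,1/4)-type tetrahedral interstitial sites with their 3-fold
    axes along the local <111>."""

    a: float
    n_cells: tuple[int, int, int]
    cage_sites: np.ndarray  # fractional, (N, 3)
    linker_sites: np.ndarray  # fractional, (M, 3)
    space_group: str = "F432"

    def cage_cartesian(self) -> np.ndarray:
        return self.cage_sites * self.a

    def linker_cartesian(self) -> np.ndarray:
        return self.linker_sites * self.a


_FCC_BASIS = np.array(
    [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
)


def build_p3_layer(
    blockA: OligomerBlock,
    blockB: OligomerBlock,
    a: float,
    z_off: float,
    phi: float,
    n_cells: int = 1,
) -> tuple[PlaneGroupLayer, AssemblyModel]:
    """Finite n_cells × n_cells patch of a two-component P3 layer.

    Block A sits at the (0,0) threefold site in the lattice plane;
    block B at (1/3, 2/3) lifted by ``z_off`` and spun by ``phi`` about
    its 3-fold axis. Both blocks must be C3 (their axes align with the
    plane-group threefold axes, normal to the layer). Translational
    copies are exact lattice translates; clashes at small spacings are
    reported downstream, not forbidden here.
    """
    for blk, label in ((blockA, "A"), (blockB, "B")):
        if blk.cyclic_order != 3:
            raise ArchitectureError(
                f"P3 layer requires C3 blocks; component {label} is C{blk.cyclic_order}"
            )
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    layer = PlaneGroupLayer(
        a=float(a),
        n_cells=int(n_cells),
        occupancy=(blockA.block_id, blockB.block_id, None),
        z_offsets=(0.0, float(z_off), 0.0),
        rotations=(0.0, float(phi), 0.0),
    )
    a1, a2 = layer.lattice_vectors()
    placedA = place_on_axis(blockA, (0, 0, 1), 0.0, 0.0)
    placedB = place_on_axis(blockB, (0, 0, 1), float(phi), 0.0)
    siteB = (1.0 / 3.0) * a1 + (2.0 / 3.0) * a2 + np.array([0.0, 0.0, float(z_off)])
    placedB = placedB.transformed(RigidTransform.from_translation(siteB))
    ids = chain_id_stream()
    chains: list[Chain] = []
    chain_map: dict[str, tuple[int, int]] = {}
    sites = []
    for ci, placed in enumerate((placedA, placedB)):
        for idx, (i, j) in enumerate(product(range(n_cells), repeat=2)):
            T = RigidTransform.from_translation(i * a1 + j * a2)
            copy = placed.transformed(T)
            for ch in copy.all_chains():
                cid = next(ids)
                chains.append(ch.with_id(cid))
                chain_map[cid] = (ci, idx)
            sites.extend(copy.bonding_sites)
    model = AssemblyModel(
        chains=chains,
        provenance={
            "architecture": "P3-layer",
            "a": float(a),
            "z_off": float(z_off),
            "phi": float(phi),
            "n_cells": int(n_cells),
            "block_ids": [blockA.block_id, blockB.block_id],
        },
        chain_map=chain_map,
        bonding_sites=sites,
        component_axes=[[placedA.axis.direction], [placedB.axis.direction]],
    )
    return layer, model


def _verify_octahedral(cage: AssemblyModel, atol: float = 1e-3) -> bool:
    """Geometric test: the cage Cα cloud maps onto itself under every
    element of the octahedral rotation group."""
    from scipy.spatial import cKDTree

    coords = cage.ca_coords()
    center = coords.mean(axis=0)
    centered = coords - center
    tree = cKDTree(centered)
    for op in build_point_group("O").elements:
        rotated = centered @ op.matrix.T
        d, _ = tree.query(rotated, k=1)
        if d.max() > atol:
            return False
    return True


def build_f432_crystal(
    cage: AssemblyModel,
    linker: OligomerBlock,
    a: float,
    n_cells: tuple[int, int, int] = (1, 1, 1),
    verify: bool = True,
) -> tuple[CrystalModel, AssemblyModel]:
    """Finite patch of an F432 crystal: octahedral cages at FCC nodes
    (cubic axes aligned to the cell axes) interconnected by C3 linkers
    at (1/4,1/4,1/4)-type tetrahedral sites, linker 3-fold along the
    local <111>. Each interior linker site has exactly 4 equidistant
    nearest cages; each interior cage engages 4 linkers tetrahedrally,
    so 4 cages + 4 linkers form each local tetrahedral complex (and one
    conventional cell holds 4 of each).
    """
    if verify and not _verify_octahedral(cage):
        raise ArchitectureError("cage is not octahedrally symmetric")
    if linker.cyclic_order != 3:
        raise ArchitectureError(f"linker must be C3, got C{linker.cyclic_order}")
    nx, ny, nz = n_cells
    if min(nx, ny, nz) < 1:
        raise ValueError("n_cells entries must be >= 1")
    cage_frac, linker_frac = [], []
    for i, j, k in product(range(nx), range(ny), range(nz)):
        t = np.array([i, j, k], dtype=float)
        for b in _FCC_BASIS:
            cage_frac.append(b + t)
        for b in _FCC_BASIS + 0.25:
            linker_frac.append(b + t)
    cage_frac = np.array(cage_frac)
    linker_frac = np.array(linker_frac)
    crystal = CrystalModel(a=float(a), n_cells=(nx, ny, nz), cage_sites=cage_frac, linker_sites=linker_frac)

    # linker placed with its cyclic axis along (1,1,1): a 3-fold of the
    # local neighbor tetrahedron (pointing through the cage at site-(1/4,1/4,1/4))
    placed_linker = place_on_axis(linker, np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0), 0.0, 0.0)
    cage_center = cage.ca_coords().mean(axis=0)

    ids = chain_id_stream()
    chains: list[Chain] = []
    chain_map: dict[str, tuple[int, int]] = {}
    sites = []
    for idx, frac in enumerate(cage_frac):
        T = RigidTransform.from_translation(frac * a - cage_center)
        for ch in cage.chains:
            cid = next(ids)
            chains.append(ch.transformed(T, chain_id=cid))
            chain_map[cid] = (0, idx)
        sites.extend(s.transformed(T) for s in cage.bonding_sites)
    for idx, frac in enumerate(linker_frac):
        T = RigidTransform.from_translation(frac * a)
        copy = placed_linker.transformed(T)
        for ch in copy.all_chains():
            cid = next(ids)
            chains.append(ch.with_id(cid))
            chain_map[cid] = (1, idx)
        sites.extend(copy.bonding_sites)
    model = AssemblyModel(
        chains=chains,
        provenance={
            "architecture": "F432-crystal",
            "a": float(a),
            "n_cells": list(n_cells),
            "block_ids": [cage.provenance.get("architecture", "cage"), linker.block_id],
        },
        chain_map=chain_map,
        bonding_sites=sites,
        component_axes=[[], [placed_linker.axis.direction]],
    )
    return crystal, model


def local_tetrahedron_counts(crystal: CrystalModel) -> tuple[int, int]:
    """(cages per linker node, linkers per cage node) coordination of
    the bonding network, measured on maximally coordinated (interior)
    sites. In F432 both are 4: four cages interconnected by four
    linkers form each local tetrahedral complex."""
    cages = crystal.cage_cartesian()
    linkers = crystal.linker_cartesian()
    bond = np.sqrt(3.0) / 4.0 * crystal.a  # cage—linker contact distance
    tol = 1e-6 * crystal.a

    def _max_coord(centers: np.ndarray, others: np.ndarray) -> int:
        best = 0
        for c in centers:
            d = np.linalg.norm(others - c, axis=1)
            best = max(best, int(np.sum(np.abs(d - bond) < tol)))
        return best

    return _max_coord(linkers, cages), _max_coord(cages, linkers)


def zone_axis_projection(model, hkl: tuple[int, int, int]) -> np.ndarray:
    """Orthographic projection of Cα coordinates onto the plane normal
    to the zone axis [hkl].

    In-plane basis (deterministic): e1 = normalized hkl × ẑ (or x̂ when
    hkl ∥ ẑ), e2 completes the right-handed triad (e1, e2, v).
    """
    hkl = np.asarray(hkl, dtype=float)
    if np.allclose(hkl, 0.0):
        raise ValueError("zone axis must be nonzero")
    v = hkl / np.linalg.norm(hkl)
    cross = np.cross(v, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(cross) < 1e-9:
        e1 = np.array([1.0, 0.0, 0.0])
    else:
        e1 = cross / np.linalg.norm(cross)
    e2 = np.cross(v, e1)
    coords = model.ca_coords() if isinstance(model, AssemblyModel) else np.asarray(model, dtype=float)
    return np.column_stack([coords @ e1, coords @ e2])


def _fcc_allowed(h: int, k: int, l: int) -> bool:
    """F-centering selection rule: h, k, l all even or all odd."""
    parities = {h % 2, k % 2, l % 2}
    return len(parities) == 1


def bragg_positions(model, q_max: float) -> list[tuple[tuple[int, ...], float]]:
    """Allowed Bragg reflections with |q| <= q_max, sorted ascending.

    Hexagonal P3 layer: q(h,k) = (4π/(√3 a))·√(h²+hk+k²).
    Cubic F lattice:    q(hkl) = (2π/a)·√(h²+k²+l²), h,k,l all even or
    all odd (face-centering extinction). One representative (hkl) per
    distinct q, the lexicographically smallest non-negative one.
    """
    if q_max <= 0:
        raise ValueError("q_max must be positive")
    found: dict[float, tuple[tuple[int, ...], float]] = {}

    def _record(hkl: tuple[int, ...], q: float) -> None:
        key = round(q, 9)
        if key not in found or hkl < found[key][0]:
            found[key] = (hkl, q)

    if isinstance(model, PlaneGroupLayer):
        pref = 4.0 * np.pi / (np.sqrt(3.0) * model.a)
        hmax = int(np.ceil(q_max / pref)) + 1
        for h in range(0, hmax + 1):
            for k in range(-hmax, hmax + 1):
                if h == 0 and k <= 0:
                    continue
                q = pref * np.sqrt(h * h + h * k + k * k)
                if q <= q_max:
                    _record((h, k), q)
    elif isinstance(model, CrystalModel):
        pref = 2.0 * np.pi / model.a
        hmax = int(np.ceil(q_max / pref)) + 1
        for h in range(0, hmax + 1):
            for k in range(0, hmax + 1):
                for l in range(0, hmax + 1):
                    if h == k == l == 0 or not _fcc_allowed(h, k, l):
                        continue
                    q = pref * np.sqrt(h * h + k * k + l * l)
                    if q <= q_max:
                        _record((h, k, l), q)
    else:
        raise TypeError("model must be a PlaneGroupLayer or CrystalModel")
    return sorted(((hkl, float(q)) for hkl, q in found.values()), key=lambda x: x[1])
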
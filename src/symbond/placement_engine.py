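"""Arrange building blocks into target architectures.

An architecture name encodes a point group plus the cyclic orders of
the components placed on its axes ("O43": octahedral group, one
component on the C4 axes, one on the C3 axes). Placement aligns each
block's cyclic axis with a representative group axis, applies the
rigid-body degrees of freedom (spin about the axis, translation along
it), and expands by coset representatives to the full assembly. Cage
closure is guaranteed by construction: the placed axes intersect at the
angles dictated by the group.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .building_blocks import BondingSite, OligomerBlock
from .geometry import Chain, RigidTransform, align_vectors_rotation, chain_id_stream, rotation_about_axis
from .symmetry_core import PointGroup, SymmetryAxis, axes_of_order, build_point_group

__all__ = [
    "ArchitectureSpec",
    "Component",
    "DOFVector",
    "AssemblyModel",
    "ArchitectureError",
    "parse_architecture",
    "component_axes",
    "place_on_axis",
    "build_cage",
    "n_positions",
    "sample_stacked_c3",
    "place_dihedral_three_component",
    "clash_check",
]

#: default inter-oligomer Cα–Cα clash cutoff (Å): typical closest
#: approach of packed backbones.
DEFAULT_CLASH_CUTOFF = 4.0


class ArchitectureError(ValueError):
    """Architecture name does not describe a realizable arrangement."""


@dataclass(frozen=True)
class Component:
    """One building-block slot: the cyclic order of the group axis it
    occupies, or ``axis_order=None`` for free asymmetric-unit placement
    (docked assemblies whose block axis is not a group axis, e.g. a D4
    cage built from trimers)."""

    axis_order: int | None
    role: str


@dataclass(frozen=True)
class DOFVector:
    """Per-component rigid-body degrees of freedom: spin phi (degrees)
    about the component's own axis and translation t (Å) along it,
    measured from the group center."""

    dofs: tuple[tuple[float, float], ...]

    @classmethod
    def of(cls, *pairs: tuple[float, float]) -> "DOFVector":
        return cls(tuple((float(p), float(t)) for p, t in pairs))

    def __post_init__(self):
        for phi, t in self.dofs:
            if t < 0:
                raise ValueError(f"translation must be >= 0, got {t}")


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    group: PointGroup
    components: tuple[Component, ...]


@dataclass
class AssemblyModel:
    """A fully expanded multi-chain placement with provenance."""

    chains: list[Chain]
    provenance: dict
    chain_map: dict[str, tuple[int, int]]  # chain_id -> (component, position index)
    bonding_sites: list[BondingSite] = field(default_factory=list)
    component_axes: list[list[np.ndarray]] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_bonding_modules(self) -> int:
        return len(self.bonding_sites)

    def ca_coords(self) -> np.ndarray:
        return np.concatenate([c.coords for c in self.chains], axis=0)

    def transformed(self, T: RigidTransform) -> "AssemblyModel":
        return AssemblyModel(
            chains=[c.transformed(T) for c in self.chains],
            provenance=dict(self.provenance),
            chain_map=dict(self.chain_map),
            bonding_sites=[s.transformed(T) for s in self.bonding_sites],
            component_axes=[[T.R @ d for d in axes] for axes in self.component_axes],
        )


_ARCH_RE = re.compile(r"^([CDTOI])([0-9]*)$")


def parse_architecture(name: str) -> ArchitectureSpec:
    """Parse an architecture name into group + component axis orders.

    ``T33``/``O43``/``O42``/``I32``: polyhedral group, one component per
    digit, placed on the axes of that order. ``Dnm`` (e.g. ``D32``):
    dihedral Dn with components on the main Cn axis and the
    perpendicular C2 axes. ``Cn``: a single Cn component. Single-digit
    dihedral names (``D4``) denote docked single-component assemblies
    whose block is expanded as a free asymmetric unit.
    """
    m = _ARCH_RE.match(name.strip())
    if not m:
        raise ArchitectureError(f"cannot parse architecture name {name!r}")
    letter, digits = m.group(1), m.group(2)
    if letter in "TOI":
        if not digits:
            raise ArchitectureError(f"{name!r}: polyhedral architecture needs component orders")
        group = build_point_group(letter)
        orders = [int(d) for d in digits]
    elif letter == "C":
        if not digits:
            raise ArchitectureError(f"{name!r}: cyclic architecture needs an order")
        group = build_point_group(f"C{int(digits)}")
        orders = [int(digits)]
    else:  # D
        if not digits:
            raise ArchitectureError(f"{name!r}: dihedral architecture needs a group order")
        n = int(digits[0])
        group = build_point_group(f"D{n}")
        if len(digits) == 1:
            # docked ASU-mode assembly (e.g. D4 from heterotrimers)
            return ArchitectureSpec(name=name.strip(), group=group, components=(Component(None, "asu"),))
        # first component on the main Cn axis, remaining digits on their orders
        orders = [n] + [int(d) for d in digits[1:]]
    components = []
    roles = "ABCDEFGH"
    for i, o in enumerate(orders):
        fam = component_axes(group, o)
        if not fam:
            avail = sorted({op.order for op in group.elements if not op.is_identity()})
            raise ArchitectureError(
                f"{name!r}: group {group.name} has no axes of order {o} (available: {avail})"
            )
        components.append(Component(axis_order=o, role=roles[i]))
    return ArchitectureSpec(name=name.strip(), group=group, components=tuple(components))


def component_axes(group: PointGroup, n: int) -> list[SymmetryAxis]:
    """Axes suitable for an order-n component: axes whose *maximum*
    rotational order is n (a C2 dimer goes on true 2-fold axes, not on
    the 2-fold subgroup of a 4-fold axis)."""
    return [a for a in axes_of_order(group, n) if a.max_order == n]


def place_on_axis(
    block: OligomerBlock,
    axis_direction: Sequence[float],
    phi: float,
    t: float,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    flip: bool = False,
) -> OligomerBlock:
    """Rigidly place a block on an oriented axis.

    The block's own +axis is mapped onto ``axis_direction`` (outward
    convention: +axis points away from the group center; ``flip``
    reverses it), the block is spun by ``phi`` about the target axis and
    its axis center is moved to ``center + t * direction``.
    """
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    own = block.axis.direction if not flip else -block.axis.direction
    R = rotation_about_axis(d, phi) @ align_vectors_rotation(own, d)
    target = np.asarray(center, dtype=float) + t * d
    T = RigidTransform(R, target - R @ block.axis_center)
    return block.transformed(T)


def _oriented_orbit(group: PointGroup, direction: np.ndarray) -> list[np.ndarray]:
    """Coset representatives: first group element mapping the oriented
    direction onto each distinct image, in deterministic element order."""
    seen: list[np.ndarray] = []
    reps: list[np.ndarray] = []
    for op in group.elements:
        u = op.matrix @ direction
        if not any(np.allclose(u, v, atol=1e-8) for v in seen):
            seen.append(u)
            reps.append(op.matrix)
    return reps


def build_cage(
    spec: ArchitectureSpec,
    blocks: Sequence[OligomerBlock],
    dofs: DOFVector,
) -> AssemblyModel:
    """Place one block per component and expand to the full assembly.

    On-axis components go on the lexicographically smallest axis of
    their order (two components of equal order take antiparallel
    orientations of the same axis, as in two-trimer tetrahedra) and are
    expanded by the |G|/n coset representatives, giving |G| chains per
    component. ASU-mode components are expanded by every group element.
    """
    if len(blocks) != len(spec.components):
        raise ArchitectureError(
            f"{spec.name}: expected {len(spec.components)} blocks, got {len(blocks)}"
        )
    if len(dofs.dofs) != len(spec.components):
        raise ArchitectureError(
            f"{spec.name}: expected {len(spec.components)} DOF pairs, got {len(dofs.dofs)}"
        )
    ids = chain_id_stream()
    chains: list[Chain] = []
    chain_map: dict[str, tuple[int, int]] = {}
    sites: list[BondingSite] = []
    component_dirs: list[list[np.ndarray]] = []
    prev_oriented: np.ndarray | None = None
    prev_order: int | None = None
    for ci, (comp, block, (phi, t)) in enumerate(zip(spec.components, blocks, dofs.dofs)):
        if comp.axis_order is None:
            # free ASU placement: spin about own axis, displace along a
            # generic direction off every group axis, expand by all elements
            generic = np.array([1.0, 0.61803398875, 0.46692]) / np.linalg.norm(
                [1.0, 0.61803398875, 0.46692]
            )
            spin = RigidTransform.from_rotation(
                rotation_about_axis(block.axis.direction, phi)
            )
            placed = block.transformed(
                RigidTransform.from_translation(t * generic).compose(spin)
            )
            reps = [op.matrix for op in spec.group.elements]
        else:
            if block.cyclic_order != comp.axis_order:
                raise ArchitectureError(
                    f"{spec.name} component {comp.role}: block {block.block_id} is "
                    f"C{block.cyclic_order}, needs C{comp.axis_order}"
                )
            fam = component_axes(spec.group, comp.axis_order)
            d = fam[0].direction.copy()
            if prev_order == comp.axis_order and prev_oriented is not None:
                d = -prev_oriented  # second component of the same order: opposite orientation
            placed = place_on_axis(block, d, phi, t)
            prev_oriented, prev_order = d, comp.axis_order
            reps = _oriented_orbit(spec.group, d)
        dirs: list[np.ndarray] = []
        for pi, R in enumerate(reps):
            T = RigidTransform.from_rotation(R)
            copy = placed.transformed(T)
            dirs.append(copy.axis.direction)
            for ch in copy.all_chains():
                cid = next(ids)
                chains.append(ch.transformed(RigidTransform.identity(), chain_id=cid))
                chain_map[cid] = (ci, pi)
            sites.extend(copy.bonding_sites)
        component_dirs.append(dirs)
    return AssemblyModel(
        chains=chains,
        provenance={
            "architecture": spec.name,
            "dofs": [list(p) for p in dofs.dofs],
            "block_ids": [b.block_id for b in blocks],
        },
        chain_map=chain_map,
        bonding_sites=sites,
        component_axes=component_dirs,
    )


def n_positions(spec: ArchitectureSpec) -> list[int]:
    """Oligomer positions per component: |G|/n on-axis, |G| for ASU."""
    out = []
    for comp in spec.components:
        if comp.axis_order is None:
            out.append(spec.group.order)
        else:
            out.append(spec.group.order // comp.axis_order)
    return out


def sample_stacked_c3(
    top: OligomerBlock,
    bottom: OligomerBlock,
    dz_range: tuple[float, float],
    dphi_range: tuple[float, float],
    steps: tuple[int, int],
) -> list[tuple[DOFVector, AssemblyModel]]:
    """Grid-scan coaxial stacking of two C3 blocks.

    The bottom block stays fixed on +z; the top block is translated dz
    along the shared axis and spun dphi about it. Every sample retains
    global C3 symmetry.
    """
    if top.cyclic_order != 3 or bottom.cyclic_order != 3:
        raise ArchitectureError("stacked-C3 sampling requires two C3 blocks")
    nz, nphi = steps
    if nz < 1 or nphi < 1:
        raise ValueError(f"step counts must be >= 1, got {steps}")
    z_vals = np.linspace(dz_range[0], dz_range[1], nz)
    phi_vals = np.linspace(dphi_range[0], dphi_range[1], nphi)
    base_bottom = place_on_axis(bottom, (0, 0, 1), 0.0, 0.0)
    out = []
    for dz in z_vals:
        for dphi in phi_vals:
            placed_top = place_on_axis(top, (0, 0, 1), float(dphi), float(dz))
            ids = chain_id_stream()
            chains, cmap = [], {}
            for ci, blk in enumerate((base_bottom, placed_top)):
                for ch in blk.all_chains():
                    cid = next(ids)
                    chains.append(ch.with_id(cid))
                    cmap[cid] = (ci, 0)
            model = AssemblyModel(
                chains=chains,
                provenance={
                    "architecture": "C3-stack",
                    "dofs": [[0.0, 0.0], [float(dphi), float(dz)]],
                    "block_ids": [bottom.block_id, top.block_id],
                },
                chain_map=cmap,
                bonding_sites=list(base_bottom.bonding_sites) + list(placed_top.bonding_sites),
                component_axes=[[base_bottom.axis.direction], [placed_top.axis.direction]],
            )
            out.append((DOFVector.of((0.0, 0.0), (float(dphi), float(dz))), model))
    return out


def place_dihedral_three_component(
    c3: OligomerBlock,
    c2: OligomerBlock,
    phi: float,
    radius: float | None = None,
) -> AssemblyModel:
    """Dihedral three-component arrangement: one C3 trimer on +z, three
    C2 dimers on perpendicular axes intersecting the C3 axis at exactly
    90°, related by the trimer's 3-fold.

    ``phi`` rotates the first C2 axis about the C3 axis; ``radius`` is
    the dimer's distance from the C3 axis along its own axis (default:
    just outside the trimer's radial extent).
    """
    if c3.cyclic_order != 3:
        raise ArchitectureError(f"first block must be C3, got C{c3.cyclic_order}")
    if c2.cyclic_order != 2:
        raise ArchitectureError(f"second block must be C2, got C{c2.cyclic_order}")
    trimer = place_on_axis(c3, (0, 0, 1), 0.0, 0.0)
    if radius is None:
        xy = trimer.ca_coords(include_modules=True)[:, :2]
        radius = float(np.linalg.norm(xy, axis=1).max()) + 10.0
    # equivariant placement: fixed reference on +x, then spun about the
    # C3 axis, so phi and phi+120 give the same assembly up to relabeling
    ref = place_on_axis(c2, (1, 0, 0), 0.0, float(radius))
    dimer0 = ref.transformed(
        RigidTransform.from_rotation(rotation_about_axis((0, 0, 1), float(phi)))
    )
    ids = chain_id_stream()
    chains, cmap, sites = [], {}, []
    dimer_dirs = []
    for ch in trimer.all_chains():
        cid = next(ids)
        chains.append(ch.with_id(cid))
        cmap[cid] = (0, 0)
    sites.extend(trimer.bonding_sites)
    for k in range(3):
        T = RigidTransform.from_rotation(rotation_about_axis((0, 0, 1), 120.0 * k))
        copy = dimer0.transformed(T)
        dimer_dirs.append(copy.axis.direction)
        for ch in copy.all_chains():
            cid = next(ids)
            chains.append(ch.with_id(cid))
            cmap[cid] = (1, k)
        sites.extend(copy.bonding_sites)
    return AssemblyModel(
        chains=chains,
        provenance={
            "architecture": "D3-three-component",
            "dofs": [[0.0, 0.0], [float(phi), float(radius)]],
            "block_ids": [c3.block_id, c2.block_id],
        },
        chain_map=cmap,
        bonding_sites=sites,
        component_axes=[[trimer.axis.direction], dimer_dirs],
    )


def clash_check(assembly: AssemblyModel, cutoff: float = DEFAULT_CLASH_CUTOFF) -> int:
    """Count unordered inter-chain Cα pairs closer than ``cutoff`` Å.

    Zero means the placement is sterically accepted.
    """
    if not assembly.chains:
        raise ValueError("empty assembly")
    coords = assembly.ca_coords()
    labels = np.concatenate(
        [np.full(len(c), i) for i, c in enumerate(assembly.chains)]
    )
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    return int(np.sum(labels[pairs[:, 0]] != labels[pairs[:, 1]]))
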
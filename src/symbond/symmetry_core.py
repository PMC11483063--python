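"""Exact rotation-group machinery for symmetric assembly design.

Point groups are generated by brute-force closure from small generator
sets and stored as explicit lists of rotation operators. Downstream
placement code only ever needs three things from a group: its element
list, its symmetry axes grouped by rotational order, and the angles at
which axes of two given orders intersect — the geometric constraint that
decides which cyclic oligomers can close a given cage architecture.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation as ScipyRotation

from .geometry import Chain, chain_id_stream, rotation_about_axis, RigidTransform

__all__ = [
    "RotationOp",
    "PointGroup",
    "SymmetryAxis",
    "build_point_group",
    "axes_of_order",
    "min_axis_angle",
    "expand_asymmetric_unit",
    "GroupNameError",
]

#: matrices closer than this are considered the same group element;
#: exact rotations accumulate <=1e-12 error per composition, so this is
#: conservative by four orders of magnitude.
ELEMENT_TOL = 1e-8

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0


class GroupNameError(ValueError):
    """Unparseable point-group name."""


def _canonical_axis(v: np.ndarray) -> np.ndarray:
    """Unit vector with the first nonzero component positive."""
    v = v / np.linalg.norm(v)
    for x in v:
        if abs(x) > 1e-9:
            return v if x > 0 else -v
    raise ValueError("zero axis")


def _rotation_angle_axis(M: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle in [0, 180] and rotation axis of a proper rotation.

    The axis sign is chosen so the rotation is right-handed about it;
    identity returns (+z, 0). Extraction is delegated to scipy's
    quaternion path, which is stable near 180 degrees where the
    antisymmetric part of the matrix vanishes.
    """
    rotvec = ScipyRotation.from_matrix(M).as_rotvec()
    angle_rad = float(np.linalg.norm(rotvec))
    if angle_rad < 1e-9:
        return 0.0, np.array([0.0, 0.0, 1.0])
    return float(np.degrees(angle_rad)), rotvec / angle_rad


def _element_order(M: np.ndarray, max_order: int = 120) -> int:
    P = np.eye(3)
    for n in range(1, max_order + 1):
        P = P @ M
        if np.allclose(P, np.eye(3), atol=ELEMENT_TOL):
            return n
    raise ValueError("matrix is not of finite small order")


@dataclass(frozen=True)
class RotationOp:
    """A proper rotation: matrix, rotation axis, order, and angle.

    ``axis`` is sign-canonicalized (first nonzero component positive)
    and ``angle`` adjusted accordingly, so equal matrices always yield
    equal (axis, angle) pairs. The identity conventionally has axis +z.
    """

    matrix: np.ndarray
    axis: np.ndarray
    order: int
    angle: float

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RotationOp":
        M = np.asarray(M, dtype=float)
        if abs(np.linalg.det(M) - 1.0) > 1e-9:
            raise ValueError("not a proper rotation (det != +1)")
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise ValueError("matrix is not orthonormal")
        angle, axis = _rotation_angle_axis(M)
        if angle == 0.0:
            return cls(M, np.array([0.0, 0.0, 1.0]), 1, 0.0)
        canon = _canonical_axis(axis)
        if np.dot(canon, axis) < 0:  # flipped sign: same rotation, angle reversed
            angle = 360.0 - angle
        return cls(M, canon, _element_order(M), angle % 360.0)

    def is_identity(self) -> bool:
        return self.order == 1


def _sort_key(op: RotationOp):
    return (round(op.angle, 6), round(op.axis[0], 9), round(op.axis[1], 9), round(op.axis[2], 9))


@dataclass(frozen=True)
class PointGroup:
    name: str
    elements: tuple[RotationOp, ...]

    @property
    def order(self) -> int:
        return len(self.elements)

    def matrices(self) -> np.ndarray:
        return np.stack([e.matrix for e in self.elements])

    def contains_matrix(self, M: np.ndarray, atol: float = ELEMENT_TOL) -> bool:
        return any(np.allclose(e.matrix, M, atol=atol) for e in self.elements)


@dataclass(frozen=True)
class SymmetryAxis:
    """An undirected rotation axis of a group.

    ``direction`` is sign-canonicalized; ``max_order`` is the largest
    rotational order of any group element about this axis.
    """

    direction: np.ndarray
    max_order: int


def _matrix_key(M: np.ndarray) -> bytes:
    return (np.round(M, 6) + 0.0).tobytes()  # +0.0 normalizes -0.0


def _closure(generators: list[np.ndarray]) -> list[np.ndarray]:
    """Brute-force closure: compose until no new elements appear."""
    elements: list[np.ndarray] = [np.eye(3)]
    keys = {_matrix_key(np.eye(3))}

    def _add(M: np.ndarray) -> bool:
        key = _matrix_key(M)
        if key in keys:
            return False
        keys.add(key)
        elements.append(M)
        return True

    for g in generators:
        _add(g)
    frontier = list(elements)
    while frontier:
        new: list[np.ndarray] = []
        for a in frontier:
            for b in elements[:]:
                for M in (a @ b, b @ a):
                    if _add(M):
                        new.append(M)
        frontier = new
        if len(elements) > 1000:
            raise RuntimeError("closure did not terminate: generators do not span a small finite group")
    return elements


_GENERATORS = {
    "T": lambda: [
        rotation_about_axis((1.0, 1.0, 1.0), 120.0),
        rotation_about_axis((0.0, 0.0, 1.0), 180.0),
    ],
    "O": lambda: [
        rotation_about_axis((1.0, 1.0, 1.0), 120.0),
        rotation_about_axis((0.0, 0.0, 1.0), 90.0),
    ],
    "I": lambda: [
        rotation_about_axis((0.0, 1.0, _GOLDEN), 72.0),
        rotation_about_axis((0.0, 0.0, 1.0), 180.0),
    ],
}

_EXPECTED_ORDER = {"T": 12, "O": 24, "I": 60}

_NAME_RE = re.compile(r"^([CD])([0-9]+)$|^([TOI])$")


def build_point_group(name: str) -> PointGroup:
    """Build the rotation point group Cn, Dn, T, O or I.

    Elements are deterministically ordered by (angle, axis); the group
    is verified closed with the exact expected order.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise GroupNameError(
            f"cannot parse point-group name {name!r}: expected Cn, Dn, T, O or I"
        )
    if m.group(3):
        letter = m.group(3)
        mats = _closure(_GENERATORS[letter]())
        if len(mats) != _EXPECTED_ORDER[letter]:
            raise RuntimeError(f"closure of {letter} gave {len(mats)} elements")
    else:
        letter, n = m.group(1), int(m.group(2))
        if n < 1:
            raise GroupNameError(f"cyclic order must be >= 1 in {name!r}")
        gens = [rotation_about_axis((0, 0, 1), 360.0 / n)]
        if letter == "D":
            gens.append(rotation_about_axis((1, 0, 0), 180.0))
        mats = _closure(gens)
        expected = n if letter == "C" else 2 * n
        if len(mats) != expected:
            raise RuntimeError(f"closure of {name} gave {len(mats)} elements")
    ops = sorted((RotationOp.from_matrix(M) for M in mats), key=_sort_key)
    return PointGroup(name=name.strip(), elements=tuple(ops))


def axes_of_order(group: PointGroup, n: int) -> list[SymmetryAxis]:
    """Distinct axes hosting an element of order exactly n.

    Antiparallel directions are merged by sign canonicalization; each
    axis reports the maximum element order found about it. Returns an
    empty list when the group has no order-n element.
    """
    if n < 1:
        raise ValueError(f"axis order must be >= 1, got {n}")
    # gather max order per distinct axis over all non-identity elements
    axis_max: list[tuple[np.ndarray, int]] = []

    def _slot(direction: np.ndarray) -> int:
        for i, (d, _) in enumerate(axis_max):
            if np.allclose(d, direction, atol=1e-8):
                return i
        axis_max.append((direction, 0))
        return len(axis_max) - 1

    for op in group.elements:
        if op.is_identity():
            continue
        i = _slot(op.axis)
        d, o = axis_max[i]
        axis_max[i] = (d, max(o, op.order))

    out = []
    for op in group.elements:
        if op.order == n:
            i = _slot(op.axis)
            d, o = axis_max[i]
            ax = SymmetryAxis(direction=d, max_order=o)
            if not any(np.allclose(ax.direction, b.direction, atol=1e-8) for b in out):
                out.append(ax)
    out.sort(key=lambda a: tuple(np.round(a.direction, 9)))
    return out


def min_axis_angle(group: PointGroup, n1: int, n2: int) -> float:
    """Smallest intersection angle (degrees, in (0, 90]) between an
    order-n1 axis and an order-n2 axis of the group.

    This is the closure constraint for two-component cages: the cyclic
    axes of the building blocks must meet at exactly this angle.
    """
    fam1 = axes_of_order(group, n1)
    fam2 = axes_of_order(group, n2)
    for n, fam in ((n1, fam1), (n2, fam2)):
        if not fam:
            avail = sorted({op.order for op in group.elements if not op.is_identity()})
            raise ValueError(
                f"group {group.name} has no axis of order {n}; available orders: {avail}"
            )
    best = None
    for a in fam1:
        for b in fam2:
            c = abs(float(np.dot(a.direction, b.direction)))
            if c > 1.0 - 1e-12:
                continue  # same axis
            ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
            if best is None or ang < best:
                best = ang
    if best is None:
        raise ValueError(
            f"all order-{n1} and order-{n2} axes of {group.name} coincide"
        )
    return float(best)


def expand_asymmetric_unit(
    group: PointGroup, chains: Sequence[Chain]
) -> list[Chain]:
    """Apply every group element to the chain set; |group| x len(chains)
    copies with fresh unique chain identifiers, in deterministic
    (element, chain) order."""
    chains = list(chains)
    if not chains:
        raise ValueError("empty asymmetric unit")
    ids = chain_id_stream()
    out = []
    for op in group.elements:
        T = RigidTransform.from_rotation(op.matrix)
        for ch in chains:
            out.append(ch.transformed(T, chain_id=next(ids)))
    return out
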
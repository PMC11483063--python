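"""Shared rigid-body geometry primitives.

Everything downstream (point groups, block placement, junction frames,
lattice generation) is built on proper rotations and rigid transforms in
Cartesian angstrom coordinates, right-handed axes, no implicit origin
shifts.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "rotation_about_axis",
    "align_vectors_rotation",
    "RigidTransform",
    "Chain",
    "chain_id_stream",
]


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length direction vector")
    return v / n


def rotation_about_axis(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Proper rotation matrix for a right-handed rotation about *axis*."""
    u = _unit(axis)
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    ux, uy, uz = u
    K = np.array([[0.0, -uz, uy], [uz, 0.0, -ux], [-uy, ux, 0.0]])
    return c * np.eye(3) + s * K + (1.0 - c) * np.outer(u, u)


def align_vectors_rotation(a: Sequence[float], b: Sequence[float]) -> np.ndarray:
    """Minimal proper rotation carrying unit direction a onto b.

    The antiparallel case is degenerate; we rotate 180 degrees about a
    deterministic perpendicular (the coordinate axis least aligned with a).
    """
    a = _unit(a)
    b = _unit(b)
    d = float(np.dot(a, b))
    if d > 1.0 - 1e-12:
        return np.eye(3)
    if d < -1.0 + 1e-12:
        pick = int(np.argmin(np.abs(a)))
        perp = np.zeros(3)
        perp[pick] = 1.0
        perp = _unit(perp - np.dot(perp, a) * a)
        return rotation_about_axis(perp, 180.0)
    axis = np.cross(a, b)
    angle = np.degrees(np.arctan2(np.linalg.norm(axis), d))
    return rotation_about_axis(axis, angle)


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t with R a proper rotation."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotation(cls, R: np.ndarray) -> "RigidTransform":
        return cls(R, np.zeros(3))

    @classmethod
    def from_translation(cls, t: Sequence[float]) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, dtype=float))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self ∘ other)(x) = self(other(x))."""
        return RigidTransform(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidTransform":
        Rinv = self.R.T
        return RigidTransform(Rinv, -Rinv @ self.t)


_SINGLE_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def chain_id_stream() -> Iterator[str]:
    """Deterministic chain identifiers: A..Z a..z 0..9 then AA, AB, ...

    Two-character identifiers require mmCIF output; the writer enforces
    that.
    """
    yield from _SINGLE_IDS
    for a, b in itertools.product(string.ascii_uppercase, repeat=2):
        yield a + b
    for a, b, c in itertools.product(string.ascii_uppercase, repeat=3):
        yield a + b + c


@dataclass
class Chain:
    """One polypeptide chain as parallel per-atom arrays.

    The design stage works at backbone (Cα) resolution, so defaults
    describe Cα carbon traces; full-atom chains read from files carry
    their own names/elements.
    """

    chain_id: str
    coords: np.ndarray
    atom_names: np.ndarray | None = None
    elements: np.ndarray | None = None
    res_ids: np.ndarray | None = None
    b_factors: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if self.atom_names is None:
            self.atom_names = np.full(n, "CA", dtype="U6")
        else:
            self.atom_names = np.asarray(self.atom_names, dtype="U6")
        if self.elements is None:
            self.elements = np.full(n, "C", dtype="U2")
        else:
            self.elements = np.asarray(self.elements, dtype="U2")
        if self.res_ids is None:
            self.res_ids = np.arange(1, n + 1)
        else:
            self.res_ids = np.asarray(self.res_ids, dtype=int)
        if self.b_factors is None:
            self.b_factors = np.zeros(n)
        else:
            self.b_factors = np.asarray(self.b_factors, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"chain {self.chain_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    def transformed(self, T: RigidTransform, chain_id: str | None = None) -> "Chain":
        return Chain(
            chain_id=self.chain_id if chain_id is None else chain_id,
            coords=T.apply(self.coords),
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            res_ids=self.res_ids.copy(),
            b_factors=self.b_factors.copy(),
        )

    def with_id(self, chain_id: str) -> "Chain":
        c = replace(self)
        c.chain_id = chain_id
        return c

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)
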
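"""Cyclic oligomer building blocks and heterodimeric bonding modules.

A building block is a Cn protein oligomer whose rotation axis gets
aligned to an architecture axis; bonding modules are the reversible
heterodimeric interfaces ("programmable bonds") rigidly grafted onto it.
The toy generator produces idealized Cn helical-bundle blocks so every
downstream stage is testable without external coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .geometry import Chain, RigidTransform, rotation_about_axis
from .symmetry_core import SymmetryAxis

__all__ = [
    "AtomRecord",
    "AttachmentFrame",
    "BondingModule",
    "BondingSite",
    "OligomerBlock",
    "make_toy_cyclic_oligomer",
    "make_toy_bonding_module",
    "detect_principal_axis",
    "graft_bonding_modules",
    "NotCyclicError",
    "GraftClashError",
]

#: grafted fragments may not approach the core closer than this (Cα–Cα, Å);
#: below the closest approach of packed backbones.
GRAFT_CLASH_CUTOFF = 2.0

#: a candidate cyclic axis is rejected if the best Cn permutation RMSD
#: exceeds this (Å).
CYCLIC_RMSD_CUTOFF = 2.0

# ideal alpha-helix Calpha trace parameters
_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # Å


class NotCyclicError(ValueError):
    """Block has no detectable cyclic symmetry axis."""


class GraftClashError(ValueError):
    """Bonding-module fragment clashes with the block core."""


@dataclass(frozen=True)
class AtomRecord:
    element: str
    name: str
    coords: np.ndarray
    residue_index: int
    chain_id: str
    b_factor: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float).reshape(3))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")


@dataclass(frozen=True)
class AttachmentFrame:
    """Right-handed orthonormal frame (origin + basis) fixing where and
    in what orientation a module attaches."""

    origin: np.ndarray
    basis: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        B = np.asarray(self.basis, dtype=float).reshape(3, 3)
        object.__setattr__(self, "basis", B)
        if not np.allclose(B @ B.T, np.eye(3), atol=1e-9):
            raise ValueError("attachment frame basis is not orthonormal")
        if np.linalg.det(B) < 0:
            raise ValueError("attachment frame basis is left-handed")

    @classmethod
    def identity(cls) -> "AttachmentFrame":
        return cls(np.zeros(3), np.eye(3))

    def as_transform(self) -> RigidTransform:
        """Local frame coordinates -> global coordinates."""
        return RigidTransform(self.basis, self.origin)

    def transformed(self, T: RigidTransform) -> "AttachmentFrame":
        return AttachmentFrame(T.apply(self.origin), T.R @ self.basis)


@dataclass(frozen=True)
class BondingModule:
    """One half of a reversible heterodimeric interface pair.

    ``fragment`` holds Cα coordinates in the module's local frame;
    ``attachment_frame`` is the frame (also local) by which the fragment
    is positioned when grafted. ``kd_molar`` records the pair's
    dissociation constant; characterized pairs span ~10 nM (tight,
    LHD101-like) to ~2 uM (weak, LHD202-like).
    """

    name: str
    partner_name: str
    fragment: np.ndarray
    attachment_frame: AttachmentFrame
    kd_molar: float = 10e-9

    def __post_init__(self):
        object.__setattr__(self, "fragment", np.asarray(self.fragment, dtype=float).reshape(-1, 3))
        if self.kd_molar <= 0:
            raise ValueError("kd_molar must be positive")


@dataclass(frozen=True)
class BondingSite:
    """A placed bonding module on a block: global frame + provenance."""

    frame: AttachmentFrame
    module_name: str
    chain_id: str

    def transformed(self, T: RigidTransform) -> "BondingSite":
        return BondingSite(self.frame.transformed(T), self.module_name, self.chain_id)


@dataclass
class OligomerBlock:
    """A cyclic oligomer with its symmetry axis and grafted bonding sites.

    ``axis``/``axis_center`` define the cyclic axis in the block's own
    coordinates (toy blocks: +z through the origin). ``module_chains``
    hold grafted fragment copies; ``hetero`` marks symmetry-broken
    occupancy (a heterotrimer carrying a single module is the same
    backbone with one occupied site).
    """

    block_id: str
    chains: list[Chain]
    cyclic_order: int
    axis: SymmetryAxis
    axis_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bonding_sites: list[BondingSite] = field(default_factory=list)
    module_chains: list[Chain] = field(default_factory=list)
    hetero: bool = False

    def __post_init__(self):
        self.axis_center = np.asarray(self.axis_center, dtype=float).reshape(3)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def all_chains(self) -> list[Chain]:
        return list(self.chains) + list(self.module_chains)

    def ca_coords(self, include_modules: bool = False) -> np.ndarray:
        chains = self.all_chains() if include_modules else self.chains
        return np.concatenate([c.coords for c in chains], axis=0)

    def transformed(self, T: RigidTransform) -> "OligomerBlock":
        return OligomerBlock(
            block_id=self.block_id,
            chains=[c.transformed(T) for c in self.chains],
            cyclic_order=self.cyclic_order,
            axis=SymmetryAxis(direction=T.R @ self.axis.direction, max_order=self.axis.max_order),
            axis_center=T.apply(self.axis_center),
            bonding_sites=[s.transformed(T) for s in self.bonding_sites],
            module_chains=[c.transformed(T) for c in self.module_chains],
            hetero=self.hetero,
        )

    def symmetry_rmsd(self) -> float:
        """Cα RMSD between the block rotated by 360/n about its axis
        (with chains cyclically relabeled) and itself."""
        n = self.cyclic_order
        if n < 2:
            return 0.0
        R = rotation_about_axis(self.axis.direction, 360.0 / n)
        c = self.axis_center
        T = RigidTransform(R, c - R @ c)
        sq, count = 0.0, 0
        for i, ch in enumerate(self.chains):
            rotated = T.apply(ch.coords)
            target = self.chains[(i + 1) % n].coords
            if len(rotated) != len(target):
                return np.inf
            sq += float(np.sum((rotated - target) ** 2))
            count += len(rotated)
        return float(np.sqrt(sq / count))


def _ideal_helix(n_res: int, phase_deg: float) -> np.ndarray:
    """Cα trace of an ideal α-helix along +z, centered at z = 0."""
    i = np.arange(n_res)
    theta = np.deg2rad(phase_deg + _HELIX_TWIST * i)
    z = _HELIX_RISE * i
    xyz = np.column_stack(
        [_HELIX_RADIUS * np.cos(theta), _HELIX_RADIUS * np.sin(theta), z - z.mean()]
    )
    return xyz


def make_toy_cyclic_oligomer(
    n: int,
    ring_radius: float = 15.0,
    helix_length: int = 30,
    seed: int = 0,
    block_id: str | None = None,
) -> OligomerBlock:
    """Idealized Cn helical-bundle building block.

    One ideal α-helix (1.5 Å rise, 100°/residue twist, 2.3 Å helical
    radius) is placed with its axis parallel to +z at ``ring_radius``
    from the origin, then replicated by exact n-fold rotation about +z.
    The seed only sets the helix phase, so blocks are deterministic and
    exactly symmetric by construction.
    """
    if n < 1:
        raise ValueError(f"cyclic order must be >= 1, got {n}")
    if helix_length < 4:
        raise ValueError(f"helix_length must be >= 4, got {helix_length}")
    if ring_radius <= 0:
        raise ValueError(f"ring_radius must be positive, got {ring_radius}")
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0.0, 360.0))
    helix = _ideal_helix(helix_length, phase) + np.array([ring_radius, 0.0, 0.0])
    chains = []
    for k in range(n):
        R = rotation_about_axis((0, 0, 1), 360.0 * k / n)
        chains.append(Chain(chain_id=chr(ord("A") + k), coords=helix @ R.T))
    return OligomerBlock(
        block_id=block_id or f"toyC{n}-r{ring_radius:g}",
        chains=chains,
        cyclic_order=n,
        axis=SymmetryAxis(direction=np.array([0.0, 0.0, 1.0]), max_order=n),
    )


def make_toy_bonding_module(
    name: str = "TOY101-A",
    partner_name: str = "TOY101-B",
    length: int = 12,
    kd_molar: float = 10e-9,
    seed: int = 0,
) -> BondingModule:
    """Synthetic stand-in for a heterodimeric bonding-module half: a
    short ideal helix whose attachment frame sits at its N-terminal end,
    local +z pointing along the helix."""
    rng = np.random.default_rng(seed)
    frag = _ideal_helix(length, float(rng.uniform(0.0, 360.0)))
    frag -= frag[0]  # frame origin at the first residue
    return BondingModule(
        name=name,
        partner_name=partner_name,
        fragment=frag,
        attachment_frame=AttachmentFrame.identity(),
        kd_molar=kd_molar,
    )


def detect_principal_axis(block: OligomerBlock) -> tuple[SymmetryAxis, np.ndarray]:
    """Detect the cyclic axis of a block from its coordinates alone.

    The rigid transform superposing chain 0 onto chain 1 of a Cn
    oligomer is a rotation by 360/n about the cyclic axis; its rotation
    axis and fixed line give direction and center. Returns
    (axis, center); the direction sign is chosen so chain 0 -> chain 1
    is a right-handed rotation by +360/n.
    """
    n = block.cyclic_order
    if n < 2 or len(block.chains) < 2:
        raise NotCyclicError("need at least two symmetric chains to detect an axis")
    A, B = block.chains[0].coords, block.chains[1].coords
    if len(A) != len(B):
        raise NotCyclicError("chains differ in length; not a homo-oligomeric ring")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    rot, _ = Rotation.align_vectors(B - cb, A - ca)
    R = rot.as_matrix()
    t = cb - R @ ca
    # rotation axis of R (angle should be ~360/n)
    rotvec = rot.as_rotvec()
    angle = np.linalg.norm(rotvec)
    if angle < 1e-8:
        raise NotCyclicError("chains are related by pure translation, not rotation")
    direction = rotvec / angle
    # fixed line: solve (I - R) c = t_perp in the plane normal to the axis
    c = np.linalg.lstsq(np.eye(3) - R, t, rcond=None)[0]
    c = c - np.dot(c, direction) * direction + np.dot(
        block.chains[0].centroid, direction
    ) * direction
    candidate = OligomerBlock(
        block_id=block.block_id,
        chains=block.chains,
        cyclic_order=n,
        axis=SymmetryAxis(direction=direction, max_order=n),
        axis_center=c,
    )
    rmsd = candidate.symmetry_rmsd()
    if not np.isfinite(rmsd) or rmsd > CYCLIC_RMSD_CUTOFF:
        raise NotCyclicError(
            f"best C{n} permutation RMSD {rmsd:.2f} Å exceeds {CYCLIC_RMSD_CUTOFF} Å: not cyclic"
        )
    return SymmetryAxis(direction=direction, max_order=n), c


def graft_bonding_modules(
    block: OligomerBlock,
    module: BondingModule,
    per_chain_frame: AttachmentFrame,
    symmetric: bool = True,
    chain_index: int = 0,
) -> OligomerBlock:
    """Rigidly graft a bonding module onto the block.

    ``per_chain_frame`` is expressed in the reference chain's (chain 0)
    coordinates, i.e. the block frame. With ``symmetric=True`` one copy
    is placed per chain, related by the block's Cn; with
    ``symmetric=False`` a single module goes on ``chain_index`` and the
    block is flagged hetero (symmetry broken by module occupancy).
    """
    n = block.cyclic_order
    targets = range(n) if symmetric else [chain_index]
    core = block.ca_coords()
    tree = cKDTree(core)
    new_sites: list[BondingSite] = []
    new_chains: list[Chain] = []
    for k in targets:
        Rk = rotation_about_axis(block.axis.direction, 360.0 * k / n)
        c = block.axis_center
        Tk = RigidTransform(Rk, c - Rk @ c)
        frame_k = per_chain_frame.transformed(Tk)
        place = frame_k.as_transform().compose(module.attachment_frame.as_transform().inverse())
        frag = place.apply(module.fragment)
        dmin = tree.query(frag, k=1)[0].min()
        if dmin < GRAFT_CLASH_CUTOFF:
            raise GraftClashError(
                f"module {module.name} on chain {k}: closest Cα–Cα approach "
                f"{dmin:.2f} Å < {GRAFT_CLASH_CUTOFF} Å"
            )
        cid = f"{block.chains[k].chain_id}m"
        new_sites.append(BondingSite(frame=frame_k, module_name=module.name, chain_id=block.chains[k].chain_id))
        new_chains.append(Chain(chain_id=cid, coords=frag))
    return OligomerBlock(
        block_id=block.block_id,
        chains=list(block.chains),
        cyclic_order=block.cyclic_order,
        axis=block.axis,
        axis_center=block.axis_center,
        bonding_sites=list(block.bonding_sites) + new_sites,
        module_chains=list(block.module_chains) + new_chains,
        hetero=block.hetero or not symmetric,
    )
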
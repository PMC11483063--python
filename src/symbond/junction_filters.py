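"""Junction-gap geometry, closure scoring, and design filter cascades.

A junction is the rigid backbone segment that must hold a building-block
core and a bonding module in a fixed relative orientation. This module
computes the rigid transform a junction must realize (the "gap"),
scores how far an achieved frame deviates from its target (the closure
error a backbone generator's tolerance setting acts on), provides
superposition RMSD, and applies the in-silico filter cascades to
tabulated design metrics.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .building_blocks import AttachmentFrame
from .geometry import RigidTransform

__all__ = [
    "JunctionGap",
    "ClosureError",
    "DesignMetrics",
    "FilterSpec",
    "FilterResult",
    "MissingMetricError",
    "gap_transform",
    "closure_error",
    "kabsch_rmsd",
    "apply_prediction_filters",
    "apply_interface_filters",
    "filter_table",
    "read_metrics_tsv",
]

#: moment arm (Å) converting rotational closure error into an
#: equivalent displacement at the far end of a junction segment.
DEFAULT_LEVER_ARM = 10.0
#: length scale (Å) making the combined closure score dimensionless and
#: comparable to backbone-generator tolerance settings (0.25 default,
#: 0.1 for tight closure).
DEFAULT_SCORE_SCALE = 10.0


class MissingMetricError(KeyError):
    """A filter clause references a metric that was not evaluated."""


@dataclass(frozen=True)
class JunctionGap:
    """The rigid transform a junction must realize, from the core
    terminus frame to the bonding-module attachment frame."""

    start_frame: AttachmentFrame
    goal_frame: AttachmentFrame
    required_transform: RigidTransform


@dataclass(frozen=True)
class ClosureError:
    d_trans: float  # Å
    d_rot: float  # degrees
    combined: float  # dimensionless

    def __post_init__(self):
        if self.d_trans < 0 or self.d_rot < 0 or self.combined < 0:
            raise ValueError("closure errors must be non-negative")


def gap_transform(start: AttachmentFrame, goal: AttachmentFrame) -> RigidTransform:
    """Rigid transform carrying ``start`` onto ``goal``: goal ∘ start⁻¹."""
    return goal.as_transform().compose(start.as_transform().inverse())


def junction_gap(start: AttachmentFrame, goal: AttachmentFrame) -> JunctionGap:
    return JunctionGap(start, goal, gap_transform(start, goal))


def closure_error(
    achieved: AttachmentFrame,
    target: AttachmentFrame,
    lever_arm: float = DEFAULT_LEVER_ARM,
    scale: float = DEFAULT_SCORE_SCALE,
) -> ClosureError:
    """Deviation of an achieved junction frame from its target.

    d_trans is the origin distance (Å); d_rot the angle (degrees) of the
    relative rotation achieved⁻¹∘target; the combined score
    (d_trans + lever_arm · d_rot[rad]) / scale is dimensionless so a
    single tolerance threshold bounds both error channels.
    """
    if lever_arm <= 0:
        raise ValueError("lever_arm must be positive")
    d_trans = float(np.linalg.norm(achieved.origin - target.origin))
    R_rel = achieved.basis.T @ target.basis
    d_rot_rad = float(Rotation.from_matrix(R_rel).magnitude())
    combined = (d_trans + lever_arm * d_rot_rad) / scale
    return ClosureError(d_trans=d_trans, d_rot=float(np.degrees(d_rot_rad)), combined=combined)


def kabsch_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimum RMSD between two corresponded point sets over proper
    rigid superpositions (rotation + translation, no reflection)."""
    A = np.asarray(A, dtype=float).reshape(-1, 3)
    B = np.asarray(B, dtype=float).reshape(-1, 3)
    if len(A) != len(B):
        raise ValueError(f"point counts differ: {len(A)} vs {len(B)}")
    if len(A) < 1:
        raise ValueError("empty point sets")
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    rot, _ = Rotation.align_vectors(Ac, Bc)
    resid = Ac - rot.apply(Bc)
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


# --- filter cascades -------------------------------------------------

_METRIC_FIELDS = (
    "plddt", "ptm", "ca_rmsd", "met_count", "sc", "ddg", "sasa",
    "clash", "unsat_hb", "sap",
)


@dataclass(frozen=True)
class DesignMetrics:
    """Per-design metric record; ``None`` marks a metric not evaluated.

    Units: plddt 0–100, ptm 0–1, ca_rmsd Å, sc 0–1, ddg kcal/mol,
    sasa Å², counts are integers, sap is the aggregation-propensity
    score change.
    """

    plddt: float | None = None
    ptm: float | None = None
    ca_rmsd: float | None = None
    met_count: float | None = None
    sc: float | None = None
    ddg: float | None = None
    sasa: float | None = None
    clash: float | None = None
    unsat_hb: float | None = None
    sap: float | None = None
    design_id: str | None = None

    def get(self, name: str) -> float | None:
        if name not in _METRIC_FIELDS:
            raise KeyError(f"unknown metric {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reasons: tuple[str, ...]  # every failing clause, or empty


_OPS = {
    ">": operator.gt,
    "<": operator.lt,
    ">=": operator.ge,
    "<=": operator.le,
    "≥": operator.ge,
    "≤": operator.le,
}


@dataclass(frozen=True)
class FilterSpec:
    """Conjunction of threshold clauses over design metrics.

    ``mode='strict'`` raises on a missing metric; ``'permissive'``
    (default) fails the row with a "missing" reason so partial tables
    remain usable. Inequalities are applied exactly as written: strict
    clauses reject boundary values.
    """

    clauses: tuple[tuple[str, str, float], ...]
    mode: str = "permissive"

    def __post_init__(self):
        for name, op, _ in self.clauses:
            if op not in _OPS:
                raise ValueError(f"unknown comparator {op!r} in clause for {name}")
            if name not in _METRIC_FIELDS:
                raise ValueError(f"unknown metric {name!r} in filter clause")
        if self.mode not in ("strict", "permissive"):
            raise ValueError(f"mode must be 'strict' or 'permissive', got {self.mode!r}")

    @classmethod
    def prediction(cls, rmsd_cut: float = 2.0, mode: str = "permissive") -> "FilterSpec":
        """Structure-prediction confidence cascade: pLDDT > 90,
        pTM > 0.80, Cα RMSD to the design model < 1.5 or 2.0 Å."""
        return cls(
            clauses=(
                ("plddt", ">", 90.0),
                ("ptm", ">", 0.80),
                ("ca_rmsd", "<", float(rmsd_cut)),
            ),
            mode=mode,
        )

    @classmethod
    def interface(cls, include_sap: bool = True, mode: str = "permissive") -> "FilterSpec":
        """Interface-quality cascade: methionine count ≤ 5, shape
        complementarity > 0.6, ddG < −20 kcal/mol, SASA < 1600 Å²,
        clash check ≤ 2, unsatisfied H-bonds ≤ 2; optionally change in
        sap score < 30 (resurfacing)."""
        clauses = [
            ("met_count", "<=", 5.0),
            ("sc", ">", 0.6),
            ("ddg", "<", -20.0),
            ("sasa", "<", 1600.0),
            ("clash", "<=", 2.0),
            ("unsat_hb", "<=", 2.0),
        ]
        if include_sap:
            clauses.append(("sap", "<", 30.0))
        return cls(clauses=tuple(clauses), mode=mode)

    def apply(self, metrics: DesignMetrics, optional: Sequence[str] = ()) -> FilterResult:
        reasons: list[str] = []
        for name, op, threshold in self.clauses:
            value = metrics.get(name)
            if value is None:
                if name in optional:
                    continue
                if self.mode == "strict":
                    raise MissingMetricError(
                        f"metric {name!r} missing (strict mode)"
                    )
                reasons.append(f"{name}: missing")
                continue
            if not _OPS[op](value, threshold):
                reasons.append(f"{name}: {value:g} fails {name} {op} {threshold:g}")
        return FilterResult(passed=not reasons, reasons=tuple(reasons))


def apply_prediction_filters(
    metrics: DesignMetrics, rmsd_cut: float = 2.0, strict: bool = False
) -> FilterResult:
    """pLDDT > 90 AND pTM > 0.80 AND Cα RMSD < rmsd_cut (1.5 or 2.0 Å)."""
    mode = "strict" if strict else "permissive"
    return FilterSpec.prediction(rmsd_cut=rmsd_cut, mode=mode).apply(metrics)


def apply_interface_filters(metrics: DesignMetrics, strict: bool = False) -> FilterResult:
    """Interface cascade exactly as printed; the sap clause only applies
    when a sap value is present."""
    mode = "strict" if strict else "permissive"
    return FilterSpec.interface(mode=mode).apply(metrics, optional=("sap",))


def filter_table(
    rows: Iterable[DesignMetrics], spec: FilterSpec
) -> tuple[list[DesignMetrics], list[str]]:
    """Batch-apply a filter spec; order-preserving survivors plus a
    per-row audit log of failing clauses."""
    survivors: list[DesignMetrics] = []
    audit: list[str] = []
    for i, row in enumerate(rows):
        label = row.design_id if row.design_id else f"row {i + 1}"
        result = spec.apply(row, optional=("sap",))
        if result.passed:
            survivors.append(row)
            audit.append(f"{label}: PASS")
        else:
            audit.append(f"{label}: FAIL [{'; '.join(result.reasons)}]")
    return survivors, audit


def read_metrics_tsv(path: str | Path) -> list[DesignMetrics]:
    """Read a header-named metrics TSV into DesignMetrics records.

    Unknown columns are ignored except ``design_id``; malformed numeric
    fields raise with the offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed metrics TSV {path}: {e}") from e
    rows: list[DesignMetrics] = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        kwargs = {}
        for name in _METRIC_FIELDS:
            if name in rec and not pd.isna(rec[name]):
                try:
                    kwargs[name] = float(rec[name])
                except (TypeError, ValueError) as e:
                    raise ValueError(
                        f"{path}, line {i + 2}, column {name!r}: "
                        f"cannot parse {rec[name]!r} as a number"
                    ) from e
        if "design_id" in rec and not pd.isna(rec["design_id"]):
            kwargs["design_id"] = str(rec["design_id"])
        rows.append(DesignMetrics(**kwargs))
    return rows
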
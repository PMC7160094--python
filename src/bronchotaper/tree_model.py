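"""Domain model for centerline-annotated airway and artery trees.

A :class:`Tree` is a rooted collection of :class:`Branch` objects.  Each
branch carries an ordered run of centerline samples (proximal to distal,
the proximal end being the bifurcation from the parent) with world-mm
positions and inner (lumen) / outer (lumen + wall) diameters.  Arteries
carry a single diameter, stored as the outer diameter with the inner one
missing.  Missing diameters are NaN, never zero.

One JSON file per subject holds both trees plus the lung volume,
phenotype label and optional visual bronchiectasis score; a flat
one-row-per-point CSV export is provided for interoperability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "TreePoint",
    "Branch",
    "Tree",
    "SubjectRecord",
    "ValidationError",
    "ParseError",
    "read_subject",
    "write_subject",
    "subject_to_frame",
    "resample_branch",
    "validate_tree",
    "validate_subject",
]

#: Nominal arc-length sampling step, mm.
SAMPLING_STEP_MM = 0.5

#: Allowed consecutive spacing after resampling, mm.
SPACING_BOUNDS_MM = (0.4, 0.6)

PHENOTYPES = ("control", "bronchiectasis", "unknown")


class ValidationError(ValueError):
    """A tree or subject violates a structural invariant."""


class ParseError(ValueError):
    """A subject file does not conform to the tree dialect."""


@dataclass(frozen=True)
class TreePoint:
    """One centerline sample: position (world mm), arc length from the
    proximal end, and inner/outer diameters (NaN = missing)."""

    position: np.ndarray
    arc_length: float
    inner_diameter: float
    outer_diameter: float


@dataclass
class Branch:
    """An ordered proximal-to-distal run of centerline samples between
    two bifurcations.

    Coordinate arrays are parallel: ``points`` is (n, 3) world mm,
    ``arc`` is the cumulative centerline arc length (mm, starting at 0),
    ``inner`` / ``outer`` are diameters in mm with NaN for missing.
    """

    branch_id: str
    parent_id: str | None
    generation: int
    points: np.ndarray
    inner: np.ndarray
    outer: np.ndarray
    arc: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: set when resampling was skipped because the branch is too short
    too_short: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.inner = np.asarray(self.inner, dtype=float)
        self.outer = np.asarray(self.outer, dtype=float)
        if self.arc is None:
            self.arc = arc_length_of(self.points)
        else:
            self.arc = np.asarray(self.arc, dtype=float)

    def __len__(self) -> int:
        return len(self.arc)

    @property
    def length_mm(self) -> float:
        return float(self.arc[-1] - self.arc[0])

    def direction(self) -> np.ndarray:
        """Unit principal direction of the centerline (first right
        singular vector of the centred point cloud)."""
        centred = self.points - self.points.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        d = vt[0]
        # orient proximal -> distal
        if np.dot(d, self.points[-1] - self.points[0]) < 0:
            d = -d
        return d

    def iter_points(self) -> Iterator[TreePoint]:
        for i in range(len(self)):
            yield TreePoint(
                position=self.points[i],
                arc_length=float(self.arc[i]),
                inner_diameter=float(self.inner[i]),
                outer_diameter=float(self.outer[i]),
            )


@dataclass
class Tree:
    """A single rooted airway or artery tree, branches keyed by id."""

    kind: str  # "airway" | "artery"
    branches: dict[str, Branch]
    root_id: str

    def __iter__(self) -> Iterator[Branch]:
        return iter(self.branches.values())

    def __len__(self) -> int:
        return len(self.branches)

    def children_of(self, branch_id: str) -> list[Branch]:
        return [b for b in self.branches.values() if b.parent_id == branch_id]

    def parent_of(self, branch: Branch) -> Branch | None:
        if branch.parent_id is None:
            return None
        return self.branches[branch.parent_id]


@dataclass
class SubjectRecord:
    """One subject: airway and artery trees, lung volume (litres),
    phenotype label, optional visual bronchiectasis sub-score (%), and
    for synthetic subjects the generator ground truth."""

    subject_id: str
    airway_tree: Tree
    artery_tree: Tree
    lung_volume: float | None
    phenotype: str = "unknown"
    visual_score: float | None = None
    ground_truth: dict | None = None
    #: isotropic factor applied by lung-volume normalization (1 = none yet)
    rescale_factor: float = 1.0


def arc_length_of(points: np.ndarray) -> np.ndarray:
    """Cumulative Euclidean arc length along a polyline, starting at 0."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


# ---------------------------------------------------------------------------
# validation


def _check_diameters(branch: Branch, kind: str) -> None:
    for name, d in (("inner", branch.inner), ("outer", branch.outer)):
        present = ~np.isnan(d)
        if np.any(~np.isfinite(d[present])) or np.any(d[present] <= 0):
            raise ValidationError(
                f"branch {branch.branch_id!r}: {name} diameters must be "
                "strictly positive and finite where present"
            )
    both = ~np.isnan(branch.inner) & ~np.isnan(branch.outer)
    if np.any(branch.outer[both] < branch.inner[both] - 1e-12):
        raise ValidationError(
            f"branch {branch.branch_id!r}: outer diameter < inner diameter"
        )
    if kind == "artery" and not np.all(np.isnan(branch.inner)):
        raise ValidationError(
            f"branch {branch.branch_id!r}: artery branches carry a single "
            "diameter in 'outer'; inner must be missing"
        )


def _check_branch(branch: Branch, kind: str, resampled: bool) -> None:
    n = len(branch)
    if n < 2:
        raise ValidationError(f"branch {branch.branch_id!r}: needs >= 2 points")
    if branch.points.shape != (n, 3):
        raise ValidationError(f"branch {branch.branch_id!r}: points must be (n, 3)")
    if len(branch.inner) != n or len(branch.outer) != n:
        raise ValidationError(
            f"branch {branch.branch_id!r}: diameter arrays must match points"
        )
    if branch.arc[0] < 0 or np.any(np.diff(branch.arc) <= 0):
        raise ValidationError(
            f"branch {branch.branch_id!r}: arc length must be non-negative "
            "and strictly increasing"
        )
    if resampled and not branch.too_short:
        lo, hi = SPACING_BOUNDS_MM
        spacing = np.diff(branch.arc)
        # the final interval may be shorter than the step
        body = spacing[:-1] if len(spacing) > 1 else spacing
        if np.any(body < lo - 1e-9) or np.any(spacing > hi + 1e-9):
            raise ValidationError(
                f"branch {branch.branch_id!r}: spacing outside "
                f"[{lo}, {hi}] mm after resampling"
            )
    _check_diameters(branch, kind)
    if branch.generation < 0:
        raise ValidationError(f"branch {branch.branch_id!r}: generation must be >= 0")


def validate_tree(tree: Tree, resampled: bool = False) -> None:
    """Check every structural invariant of a tree; raise
    :class:`ValidationError` naming the offending branch."""
    if tree.kind not in ("airway", "artery"):
        raise ValidationError(f"unknown tree kind {tree.kind!r}")
    if not tree.branches:
        raise ValidationError(f"{tree.kind} tree has no branches")
    if tree.root_id not in tree.branches:
        raise ValidationError(f"root id {tree.root_id!r} not among branches")

    for branch in tree:
        _check_branch(branch, tree.kind, resampled)

    # parent links form a single rooted tree
    for branch in tree:
        if branch.parent_id is None:
            if branch.branch_id != tree.root_id:
                raise ValidationError(
                    f"branch {branch.branch_id!r}: parentless but not the root"
                )
            if branch.generation != 0:
                raise ValidationError(
                    f"branch {branch.branch_id!r}: root generation must be 0"
                )
            continue
        if branch.parent_id not in tree.branches:
            raise ValidationError(
                f"branch {branch.branch_id!r}: unknown parent {branch.parent_id!r}"
            )
        parent = tree.branches[branch.parent_id]
        if branch.generation != parent.generation + 1:
            raise ValidationError(
                f"branch {branch.branch_id!r}: generation "
                f"{branch.generation} != parent generation + 1"
            )

    # reachability & acyclicity: walk up from every branch
    for branch in tree:
        seen = set()
        current: Branch | None = branch
        while current is not None:
            if current.branch_id in seen:
                raise ValidationError(
                    f"branch {branch.branch_id!r}: cycle in parent links"
                )
            seen.add(current.branch_id)
            if current.parent_id is None:
                break
            current = tree.branches.get(current.parent_id)
        if current is None or current.branch_id != tree.root_id:
            raise ValidationError(
                f"branch {branch.branch_id!r}: not connected to root"
            )

    # attachment: each child's first point within 1 mm of the parent line
    for branch in tree:
        if branch.parent_id is None:
            continue
        parent = tree.branches[branch.parent_id]
        gap = np.min(np.linalg.norm(parent.points - branch.points[0], axis=1))
        if gap > 1.0 + 1e-9:
            raise ValidationError(
                f"branch {branch.branch_id!r}: first point {gap:.2f} mm from "
                "parent centerline (> 1 mm)"
            )


def validate_subject(subject: SubjectRecord, resampled: bool = False) -> None:
    if not subject.subject_id:
        raise ValidationError("subject_id must be non-empty")
    if subject.lung_volume is not None and not (subject.lung_volume > 0):
        raise ValidationError(
            f"subject {subject.subject_id!r}: lung_volume must be > 0"
        )
    if subject.phenotype not in PHENOTYPES:
        raise ValidationError(
            f"subject {subject.subject_id!r}: unknown phenotype "
            f"{subject.phenotype!r}"
        )
    if subject.visual_score is not None and not (0 <= subject.visual_score <= 100):
        raise ValidationError(
            f"subject {subject.subject_id!r}: visual_score outside [0, 100]"
        )
    if subject.airway_tree.kind != "airway" or subject.artery_tree.kind != "artery":
        raise ValidationError(
            f"subject {subject.subject_id!r}: tree kinds must be airway/artery"
        )
    validate_tree(subject.airway_tree, resampled=resampled)
    validate_tree(subject.artery_tree, resampled=resampled)


# ---------------------------------------------------------------------------
# resampling


def resample_branch(branch: Branch, step: float = SAMPLING_STEP_MM) -> Branch:
    """Resample a branch to uniform arc-length spacing.

    Positions and diameters are linearly interpolated along arc length;
    the final interval may be shorter than ``step`` so the total arc
    length is preserved exactly.  A branch shorter than one step is
    returned unchanged with ``too_short`` set.
    """
    if len(branch) < 2:
        raise ValidationError(f"branch {branch.branch_id!r}: needs >= 2 points")
    length = branch.length_mm
    if length < step:
        return replace(branch, too_short=True)
    arc0 = branch.arc - branch.arc[0]
    n_full = int(math.floor(length / step + 1e-9))
    grid = np.arange(n_full + 1) * step
    if length - grid[-1] > 1e-9:
        grid = np.append(grid, length)
    pts = np.column_stack([np.interp(grid, arc0, branch.points[:, k]) for k in range(3)])
    inner = _interp_keep_nan(grid, arc0, branch.inner)
    outer = _interp_keep_nan(grid, arc0, branch.outer)
    return Branch(
        branch_id=branch.branch_id,
        parent_id=branch.parent_id,
        generation=branch.generation,
        points=pts,
        inner=inner,
        outer=outer,
        arc=grid,
    )


def _interp_keep_nan(grid: np.ndarray, arc: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Interpolate, keeping fully-missing channels missing and flagging
    samples that fall between a present and a missing neighbour."""
    if np.all(np.isnan(values)):
        return np.full_like(grid, np.nan)
    if not np.any(np.isnan(values)):
        return np.interp(grid, arc, values)
    out = np.interp(grid, arc, values)
    # any window touching a NaN propagates NaN through np.interp already
    # only when the NaN is an endpoint; enforce it for interior NaNs too
    nan_idx = np.where(np.isnan(values))[0]
    for i in nan_idx:
        lo = arc[max(i - 1, 0)]
        hi = arc[min(i + 1, len(arc) - 1)]
        out[(grid > lo) & (grid < hi)] = np.nan
        out[np.isclose(grid, arc[i])] = np.nan
    return out


def resample_tree(tree: Tree, step: float = SAMPLING_STEP_MM) -> Tree:
    return Tree(
        kind=tree.kind,
        branches={bid: resample_branch(b, step) for bid, b in tree.branches.items()},
        root_id=tree.root_id,
    )


def resample_subject(subject: SubjectRecord, step: float = SAMPLING_STEP_MM) -> SubjectRecord:
    return replace(
        subject,
        airway_tree=resample_tree(subject.airway_tree, step),
        artery_tree=resample_tree(subject.artery_tree, step),
    )


# ---------------------------------------------------------------------------
# JSON dialect


def _num_or_none(x: float) -> float | None:
    return None if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)


def _branch_to_record(branch: Branch) -> dict:
    pts = [
        [
            float(p[0]),
            float(p[1]),
            float(p[2]),
            _num_or_none(float(i)),
            _num_or_none(float(o)),
        ]
        for p, i, o in zip(branch.points, branch.inner, branch.outer)
    ]
    return {
        "branch_id": branch.branch_id,
        "parent_id": branch.parent_id,
        "generation": branch.generation,
        "points": pts,
    }


def _branch_from_record(rec: dict, where: str) -> Branch:
    try:
        pts = np.asarray(
            [[row[0], row[1], row[2]] for row in rec["points"]], dtype=float
        )
        inner = np.asarray(
            [np.nan if row[3] is None else float(row[3]) for row in rec["points"]]
        )
        outer = np.asarray(
            [np.nan if row[4] is None else float(row[4]) for row in rec["points"]]
        )
        return Branch(
            branch_id=str(rec["branch_id"]),
            parent_id=None if rec["parent_id"] is None else str(rec["parent_id"]),
            generation=int(rec["generation"]),
            points=pts,
            inner=inner,
            outer=outer,
        )
    except (KeyError, IndexError, TypeError, ValueError) as err:
        raise ParseError(f"malformed branch record in {where}: {err}") from err


def _tree_from_records(records: list, kind: str, where: str) -> Tree:
    branches = {}
    for rec in records:
        b = _branch_from_record(rec, where)
        if b.branch_id in branches:
            raise ParseError(f"duplicate branch id {b.branch_id!r} in {where}")
        branches[b.branch_id] = b
    roots = [b.branch_id for b in branches.values() if b.parent_id is None]
    if len(roots) != 1:
        raise ValidationError(
            f"{where}: expected exactly one root branch, found {len(roots)}"
        )
    return Tree(kind=kind, branches=branches, root_id=roots[0])


def write_subject(subject: SubjectRecord, path: str | Path) -> None:
    """Serialize a validated subject to the one-file-per-subject JSON
    dialect.  Missing values are written as explicit null."""
    validate_subject(subject)
    doc = {
        "subject_id": subject.subject_id,
        "lung_volume_L": _num_or_none(subject.lung_volume),
        "phenotype": subject.phenotype,
        "visual_score": _num_or_none(subject.visual_score),
        "rescale_factor": subject.rescale_factor,
        "airway": [_branch_to_record(b) for b in subject.airway_tree],
        "artery": [_branch_to_record(b) for b in subject.artery_tree],
        "ground_truth": subject.ground_truth,
    }
    Path(path).write_text(json.dumps(doc))


def read_subject(path: str | Path) -> SubjectRecord:
    """Read and fully validate a subject from the JSON dialect."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise ParseError(f"{path}: not valid JSON: {err}") from err
    for key in ("subject_id", "lung_volume_L", "phenotype", "airway", "artery"):
        if key not in doc:
            raise ParseError(f"{path}: missing required field {key!r}")
    subject = SubjectRecord(
        subject_id=str(doc["subject_id"]),
        airway_tree=_tree_from_records(doc["airway"], "airway", f"{path} (airway)"),
        artery_tree=_tree_from_records(doc["artery"], "artery", f"{path} (artery)"),
        lung_volume=_num_or_none(doc["lung_volume_L"]),
        phenotype=str(doc["phenotype"]),
        visual_score=_num_or_none(doc.get("visual_score")),
        ground_truth=doc.get("ground_truth"),
        rescale_factor=float(doc.get("rescale_factor", 1.0)),
    )
    validate_subject(subject)
    return subject


def subject_to_frame(subject: SubjectRecord) -> pd.DataFrame:
    """Flat one-row-per-point export (CSV-friendly)."""
    rows = []
    for tree in (subject.airway_tree, subject.artery_tree):
        for b in tree:
            for i in range(len(b)):
                rows.append(
                    {
                        "subject_id": subject.subject_id,
                        "tree_kind": tree.kind,
                        "branch_id": b.branch_id,
                        "parent_id": b.parent_id,
                        "generation": b.generation,
                        "arc_mm": b.arc[i],
                        "x": b.points[i, 0],
                        "y": b.points[i, 1],
                        "z": b.points[i, 2],
                        "inner_mm": b.inner[i],
                        "outer_mm": b.outer[i],
                    }
                )
    return pd.DataFrame(rows)
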
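"""Seeded synthetic bronchial-tree subjects, cohorts and voxel phantoms.

The generator builds binary bifurcating airway trees whose diameters
follow the two tapering laws the biomarkers measure:

* along each branch the inner diameter decays linearly,
  ``d(x) = d0 * (1 - t/100 * x)`` with the true intra-branch tapering
  ``t`` in %/mm drawn per branch from a truncated normal;
* across each bifurcation the child's *mean* diameter sits ``b`` percent
  below the parent's mean diameter, ``b`` drawn per child, so the drawn
  ``b`` is exactly the true inter-branch tapering of that branch.

Outer diameter is inner times ``1 + wall_fraction``.  A companion artery
tree mirrors the airway topology with offset centerlines and a diameter
keyed to the airway outer diameter.  Measurement noise, occasional gross
multiplicative outliers (segmentation-error analogues) and a subject
lung volume complete the record; every drawn ``t`` and ``b`` is kept as
ground truth.  Identical parameters and seed give bit-identical output.

The bronchiectasis phenotype is reduced tapering distributed uniformly
across the tree (the airway dilates relative to its artery; arteries are
untouched), not focal dilation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .tree_model import (
    Branch,
    SubjectRecord,
    Tree,
    ValidationError,
    validate_subject,
)

__all__ = [
    "GeneratorParams",
    "GenerationError",
    "Phantom",
    "generate_subject",
    "generate_cohort",
    "rasterize_phantom",
]


class GenerationError(ValueError):
    """Parameters produced a non-physical tree (e.g. vanishing diameter)."""


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort generator.

    Tapering means/SDs are in the units of the biomarkers themselves
    (intra: % per mm; inter: %).  Phenotype defaults come from the
    matched control / bronchiectasis cohort medians the biomarkers are
    meant to discriminate: control intra 1.56 %/mm and inter 38.5 %,
    disease intra 0.89 %/mm and inter 32.3 %.  Subject-level SDs set the
    between-subject spread of each subject's own mean tapering; the
    branch-level SDs set within-subject spread across branches.
    """

    n_generations: int = 6
    root_inner_diameter: float = 10.0
    wall_fraction: float = 0.3
    intra_taper_mean: float = 1.56
    intra_taper_sd: float = 0.35
    intra_subject_sd: float = 0.25
    inter_taper_mean: float = 38.5
    inter_taper_sd: float = 6.0
    inter_subject_sd: float = 3.0
    branch_length_over_diameter: float = 3.0
    branching_angle_deg: tuple[float, float] = (35.0, 10.0)
    artery_over_airway_outer: float = 1.0 / 1.16
    #: healthy-airway tapering (intra %/mm, inter %) that the companion
    #: arteries follow; keeping it at the control values means a
    #: reduced-tapering airway dilates *relative to its artery*, raising
    #: the AA ratio, while arteries themselves are untouched by disease
    artery_reference_taper: tuple[float, float] = (1.56, 38.5)
    artery_offset_mm: float = 2.0
    diameter_noise_sd: float = 0.05
    outlier_fraction: float = 0.02
    outlier_magnitude: tuple[float, float] = (1.5, 3.0)
    lung_volume_L: tuple[float, float] = (4.0, 0.6)
    step_mm: float = 0.5
    seed: int = 0

    # truncation bounds keeping draws physical
    intra_bounds: tuple[float, float] = (-1.0, 5.0)
    inter_bounds: tuple[float, float] = (5.0, 60.0)

    @classmethod
    def control(cls, **overrides) -> "GeneratorParams":
        return cls(**overrides)

    @classmethod
    def bronchiectasis(cls, **overrides) -> "GeneratorParams":
        overrides.setdefault("intra_taper_mean", 0.89)
        overrides.setdefault("inter_taper_mean", 32.3)
        return cls(**overrides)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return float(x)
    raise GenerationError(
        f"truncated normal({mean}, {sd}) in ({lo}, {hi}) failed to draw"
    )


def _round_to_step(length: float, step: float) -> float:
    return max(step, round(length / step) * step)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass
class _Stub:
    branch_id: str
    parent_id: str | None
    generation: int
    start: np.ndarray
    direction: np.ndarray
    u: np.ndarray  # in-plane perpendicular, seeds the bifurcation plane
    d0: float
    t: float
    b: float | None  # true interBT; None at the root
    length: float | None = None  # pre-solved branch length, mm


def _grow_branch(stub: _Stub, p: GeneratorParams) -> tuple[Branch, float, float]:
    """Realize a stub as a Branch; return it with (mean inner, length)."""
    length = stub.length if stub.length is not None else _round_to_step(
        p.branch_length_over_diameter * stub.d0, p.step_mm
    )
    distal = stub.d0 * (1.0 - stub.t / 100.0 * length)
    if distal <= 0.05 or stub.d0 <= 0.05:
        raise GenerationError(
            f"branch {stub.branch_id!r}: diameter vanishes at depth "
            f"{stub.generation}; use fewer generations or weaker tapering"
        )
    grid = np.arange(int(round(length / p.step_mm)) + 1) * p.step_mm
    inner = stub.d0 * (1.0 - stub.t / 100.0 * grid)
    outer = inner * (1.0 + p.wall_fraction)
    pts = stub.start + grid[:, None] * stub.direction
    branch = Branch(
        branch_id=stub.branch_id,
        parent_id=stub.parent_id,
        generation=stub.generation,
        points=pts,
        inner=inner,
        outer=outer,
        arc=grid,
    )
    return branch, float(inner.mean()), length


def _build_airway(p: GeneratorParams, rng: np.random.Generator
                  ) -> tuple[dict[str, Branch], dict[str, dict], dict[str, float]]:
    """Depth-first recursive construction; returns branches, per-branch
    ground truth {'t': %/mm, 'b': % or None}, and the healthy-reference
    mean calibre per branch (the cascade the arteries follow)."""
    lo_t, hi_t = p.intra_bounds
    lo_b, hi_b = p.inter_bounds
    t_subj = _truncated_normal(rng, p.intra_taper_mean, p.intra_subject_sd, lo_t, hi_t)
    b_subj = _truncated_normal(rng, p.inter_taper_mean, p.inter_subject_sd, lo_b, hi_b)
    ang_mean, ang_sd = p.branching_angle_deg

    branches: dict[str, Branch] = {}
    truth: dict[str, dict] = {}
    ref_means: dict[str, float] = {}
    # arteries taper at the healthy rate: the subject's own draws plus
    # the gap between the healthy reference and this phenotype's means
    d_inter = p.artery_reference_taper[1] - p.inter_taper_mean

    def grow(stub: _Stub, ref_mean: float) -> None:
        branch, mean_inner, length = _grow_branch(stub, p)
        branches[stub.branch_id] = branch
        truth[stub.branch_id] = {"t": stub.t, "b": stub.b}
        ref_means[stub.branch_id] = ref_mean
        if stub.generation + 1 >= p.n_generations:
            return
        # bifurcation plane rotates roughly 90 degrees per generation
        phi = math.radians(rng.normal(90.0, 20.0))
        v = np.cross(stub.direction, stub.u)
        u_plane = _unit(math.cos(phi) * stub.u + math.sin(phi) * v)
        end = branch.points[-1]
        for side, tag in ((1.0, "0"), (-1.0, "1")):
            theta = math.radians(
                _truncated_normal(rng, ang_mean, ang_sd, 5.0, 80.0)
            )
            cdir = _unit(
                math.cos(theta) * stub.direction + side * math.sin(theta) * u_plane
            )
            cu = _unit(stub.direction - np.dot(stub.direction, cdir) * cdir)
            b = _truncated_normal(rng, b_subj, p.inter_taper_sd, lo_b, hi_b)
            t = _truncated_normal(rng, t_subj, p.intra_taper_sd, lo_t, hi_t)
            target_mean = mean_inner * (1.0 - b / 100.0)
            child_len = _round_to_step(
                p.branch_length_over_diameter * target_mean, p.step_mm
            )
            denom = 1.0 - t / 100.0 * child_len / 2.0
            if denom <= 0.2:
                raise GenerationError(
                    f"branch {stub.branch_id}{tag}: tapering too steep for "
                    "branch length; use fewer generations"
                )
            grow(
                _Stub(
                    branch_id=stub.branch_id + tag,
                    parent_id=stub.branch_id,
                    generation=stub.generation + 1,
                    start=end,
                    direction=cdir,
                    u=cu,
                    d0=target_mean / denom,
                    t=t,
                    b=b,
                    length=child_len,
                ),
                ref_mean * (1.0 - min(b + d_inter, 95.0) / 100.0),
            )

    root_t = _truncated_normal(rng, t_subj, p.intra_taper_sd, lo_t, hi_t)
    d_intra = p.artery_reference_taper[0] - p.intra_taper_mean
    root_len = _round_to_step(
        p.branch_length_over_diameter * p.root_inner_diameter, p.step_mm
    )
    root_ref_mean = p.root_inner_diameter * (
        1.0 - (root_t + d_intra) / 100.0 * root_len / 2.0
    )
    grow(
        _Stub(
            branch_id="b",
            parent_id=None,
            generation=0,
            start=np.zeros(3),
            direction=np.array([0.0, 0.0, -1.0]),
            u=np.array([1.0, 0.0, 0.0]),
            d0=p.root_inner_diameter,
            t=root_t,
            b=None,
        ),
        root_ref_mean,
    )
    return branches, truth, ref_means


def _build_artery(airway: dict[str, Branch], ref_means: dict[str, float],
                  truth: dict[str, dict], p: GeneratorParams,
                  rng: np.random.Generator) -> dict[str, Branch]:
    """Companion arteries: airway topology, centerlines shifted by a
    subject-constant offset vector, single diameter (stored in `outer`,
    inner missing).

    Artery calibre follows the healthy-reference cascade at the same
    tree position: the subject's own tapering draws shifted by the gap
    between the healthy reference and the phenotype means.  For a
    control phenotype the gap is zero and arteries mirror their
    airways; for reduced-tapering disease the arteries keep tapering at
    the healthy rate, so the airway dilates relative to its artery,
    increasingly towards the periphery.
    """
    offset = _unit(rng.normal(size=3)) * p.artery_offset_mm
    d_intra = p.artery_reference_taper[0] - p.intra_taper_mean
    arteries: dict[str, Branch] = {}
    for bid, b in airway.items():
        factor = rng.normal(1.0, 0.05)
        t_ref = truth[bid]["t"] + d_intra
        length = float(b.arc[-1] - b.arc[0])
        denom = 1.0 - t_ref / 100.0 * length / 2.0
        ref_d0 = ref_means[bid] / denom
        ref_inner = ref_d0 * (1.0 - t_ref / 100.0 * (b.arc - b.arc[0]))
        ref_outer = ref_inner * (1.0 + p.wall_fraction)
        arteries["A" + bid] = Branch(
            branch_id="A" + bid,
            parent_id=None if b.parent_id is None else "A" + b.parent_id,
            generation=b.generation,
            points=b.points + offset,
            inner=np.full(len(b), np.nan),
            outer=ref_outer * p.artery_over_airway_outer * factor,
            arc=b.arc.copy(),
        )
    return arteries


def _noisy_diameters(tree: dict[str, Branch], p: GeneratorParams,
                     rng: np.random.Generator, airway: bool) -> None:
    """Add per-point Gaussian noise and multiplicative outliers in place.

    Noise is applied to the lumen and to the wall thickness separately so
    the measured outer never drops below the measured inner; an outlier
    scales the whole cross-section, like a segmentation leak.
    """
    lo_m, hi_m = p.outlier_magnitude
    for b in tree.values():
        n = len(b)
        if airway:
            inner = b.inner + rng.normal(0.0, p.diameter_noise_sd, n)
            wall = (b.outer - b.inner) + rng.normal(0.0, p.diameter_noise_sd, n)
            inner = np.maximum(inner, 0.05)
            wall = np.maximum(wall, 0.02)
            spikes = rng.random(n) < p.outlier_fraction
            factor = np.where(spikes, rng.uniform(lo_m, hi_m, n), 1.0)
            b.inner = inner * factor
            b.outer = (inner + wall) * factor
        else:
            d = b.outer + rng.normal(0.0, p.diameter_noise_sd, n)
            d = np.maximum(d, 0.05)
            spikes = rng.random(n) < p.outlier_fraction
            factor = np.where(spikes, rng.uniform(lo_m, hi_m, n), 1.0)
            b.outer = d * factor


def generate_subject(params: GeneratorParams, phenotype: str = "control",
                     subject_id: str = "synthetic") -> SubjectRecord:
    """Generate one fully validated synthetic subject.

    The tree is constructed at the 4-L reference scale, then scaled
    isotropically by ``(V/4)^(1/3)`` for the drawn lung volume ``V`` so
    that lung-volume normalization is exercised downstream.  Ground
    truth stores each branch's true tapering at the reference scale,
    i.e. the values the pipeline recovers after normalization.
    """
    rng = np.random.default_rng(params.seed)
    airway, truth, ref_means = _build_airway(params, rng)
    vol_mean, vol_sd = params.lung_volume_L
    lung_volume = _truncated_normal(rng, vol_mean, vol_sd, 1.0, 9.0) \
        if vol_sd > 0 else float(vol_mean)
    artery = _build_artery(airway, ref_means, truth, params, rng)
    _noisy_diameters(airway, params, rng, airway=True)
    _noisy_diameters(artery, params, rng, airway=False)

    scale = (lung_volume / 4.0) ** (1.0 / 3.0)
    for tree in (airway, artery):
        for b in tree.values():
            b.points = b.points * scale
            b.inner = b.inner * scale
            b.outer = b.outer * scale
            b.arc = b.arc * scale

    # visual severity score loosely tracking loss of intra-branch tapering
    # relative to the control reference, as a correlation covariate
    t_values = [v["t"] for v in truth.values()]
    score = (1.56 - float(np.mean(t_values))) * 20.0 + abs(rng.normal(0.0, 2.0))
    visual_score = float(min(max(score, 0.0), 100.0))

    subject = SubjectRecord(
        subject_id=subject_id,
        airway_tree=Tree(kind="airway", branches=airway, root_id="b"),
        artery_tree=Tree(kind="artery", branches=artery, root_id="Ab"),
        lung_volume=lung_volume,
        phenotype=phenotype,
        visual_score=visual_score,
        ground_truth={
            "per_branch": truth,
            "subject_scale": scale,
            "lung_volume_L": lung_volume,
            "seed": params.seed,
        },
    )
    validate_subject(subject)
    return subject


def generate_cohort(n_control: int, n_disease: int,
                    control_params: GeneratorParams | None = None,
                    disease_params: GeneratorParams | None = None,
                    seed: int = 0) -> list[SubjectRecord]:
    """Generate a two-phenotype cohort with per-subject seeds derived
    deterministically (master seed + subject index), so any subject can
    be regenerated alone."""
    if n_control < 1 or n_disease < 1:
        raise ValueError("need at least one subject per phenotype")
    control_params = control_params or GeneratorParams.control()
    disease_params = disease_params or GeneratorParams.bronchiectasis()
    subjects = []
    for i in range(n_control):
        p = replace(control_params, seed=seed + i)
        subjects.append(generate_subject(p, "control", f"control_{i:02d}"))
    for j in range(n_disease):
        p = replace(disease_params, seed=seed + n_control + j)
        subjects.append(
            generate_subject(p, "bronchiectasis", f"disease_{j:02d}")
        )
    return subjects


# ---------------------------------------------------------------------------
# voxel phantoms


@dataclass
class Phantom:
    """Labelled tube-tree volume: 0 background, 1 wall, 2 lumen.

    ``labels`` is indexed [i, j, k] along world x, y, z; the world
    position of voxel centre (i, j, k) is ``origin + voxel_mm * (i, j, k)``.
    """

    labels: np.ndarray
    voxel_mm: float
    origin: np.ndarray

    LUMEN = 2
    WALL = 1

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_mm

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.labels.astype(np.uint8), affine), str(path))

    def to_metaimage(self, path) -> None:
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(self.labels.T))
        img.SetSpacing((self.voxel_mm,) * 3)
        img.SetOrigin(tuple(float(x) for x in self.origin))
        sitk.WriteImage(img, str(path))


def load_phantom(path) -> Phantom:
    """Read a phantom back from NIfTI, recovering spacing and origin."""
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    voxel = float(affine[0, 0])
    return Phantom(
        labels=np.asarray(img.dataobj, dtype=np.uint8),
        voxel_mm=voxel,
        origin=affine[:3, 3].copy(),
    )


def rasterize_phantom(tree: Tree, voxel_mm: float, margin_mm: float = 2.0) -> Phantom:
    """Rasterize a tree into an isotropic labelled volume.

    A voxel is foreground iff its centre lies within the local tube
    radius — linearly interpolated along the centerline — of some branch
    segment (flat-capped tubes: the centre must project onto the
    segment).  Lumen (inner radius) overrides wall (outer radius).
    """
    if not tree.branches:
        raise ValidationError("cannot rasterize an empty tree")
    # resolution precondition: voxel no coarser than half the smallest radius
    for b in tree:
        for d in (b.inner, b.outer):
            present = d[~np.isnan(d)]
            if present.size and voxel_mm > present.min() / 4.0 + 1e-12:
                raise ValidationError(
                    f"voxel {voxel_mm} mm too coarse for branch "
                    f"{b.branch_id!r} (min diameter {present.min():.2f} mm)"
                )

    all_pts = np.vstack([b.points for b in tree])
    max_r = max(
        float(np.nanmax(b.outer)) if not np.all(np.isnan(b.outer))
        else float(np.nanmax(b.inner))
        for b in tree
    ) / 2.0
    lo = all_pts.min(axis=0) - max_r - margin_mm
    hi = all_pts.max(axis=0) + max_r + margin_mm
    shape = np.ceil((hi - lo) / voxel_mm).astype(int) + 1
    labels = np.zeros(shape, dtype=np.uint8)

    for b in tree:
        radius_in = b.inner / 2.0
        radius_out = np.where(np.isnan(b.outer), b.inner, b.outer) / 2.0
        for s in range(len(b) - 1):
            p0, p1 = b.points[s], b.points[s + 1]
            r0o, r1o = radius_out[s], radius_out[s + 1]
            r0i, r1i = radius_in[s], radius_in[s + 1]
            _mark_segment(labels, lo, voxel_mm, p0, p1, r0o, r1o, Phantom.WALL)
            if not (np.isnan(r0i) or np.isnan(r1i)):
                _mark_segment(labels, lo, voxel_mm, p0, p1, r0i, r1i, Phantom.LUMEN)
    return Phantom(labels=labels, voxel_mm=voxel_mm, origin=lo)


def _mark_segment(labels: np.ndarray, origin: np.ndarray, voxel: float,
                  p0: np.ndarray, p1: np.ndarray, r0: float, r1: float,
                  value: int) -> None:
    rmax = max(r0, r1)
    box_lo = np.maximum(
        np.floor((np.minimum(p0, p1) - rmax - origin) / voxel).astype(int), 0
    )
    box_hi = np.minimum(
        np.ceil((np.maximum(p0, p1) + rmax - origin) / voxel).astype(int),
        np.asarray(labels.shape) - 1,
    )
    if np.any(box_hi < box_lo):
        return
    axes = [np.arange(box_lo[k], box_hi[k] + 1) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    centres = origin + grid * voxel
    seg = p1 - p0
    seg_len2 = float(np.dot(seg, seg))
    if seg_len2 == 0:
        return
    rel = centres - p0
    u = np.einsum("ijkl,l->ijk", rel, seg) / seg_len2
    inside_slab = (u >= 0.0) & (u <= 1.0)
    proj = p0 + u[..., None] * seg
    dist2 = np.sum((centres - proj) ** 2, axis=-1)
    radius = r0 + np.clip(u, 0.0, 1.0) * (r1 - r0)
    hit = inside_slab & (dist2 <= radius**2)
    sub = labels[
        box_lo[0]: box_hi[0] + 1,
        box_lo[1]: box_hi[1] + 1,
        box_lo[2]: box_hi[2] + 1,
    ]
    if value == Phantom.LUMEN:
        sub[hit] = value
    else:
        sub[hit & (sub == 0)] = value
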
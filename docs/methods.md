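# Methods

`bronchotaper` quantifies how quickly airways narrow along the bronchial
tree and compares that narrowing between cohorts. This note records the
model, the estimators, the synthetic data the package tests itself on,
and the numerical choices that were genuinely open.

## Biomarkers

**Intra-branch tapering (intraBT).** Along one branch (the run of
centerline between two bifurcations) diameters are sampled every
0.5 mm. A line *y = m·x + n* is fitted to diameter against arc length
and

    intraBT = −m / n × 100    [% per mm]

so intraBT = 2 means the diameter shrinks by 2% of its proximal value
per millimetre; negative values mean distal flaring and are retained —
dilation is the signal of interest. The fit uses iteratively
reweighted least squares with Tukey biweight weights (tuning constant
4.685, robust scale = MAD/0.6745, at most 50 iterations, convergence
when no coefficient moves by more than 1e-12). The iteration starts
from the Theil–Sen line (median of pairwise slopes): a plain
least-squares start can sit so far from the bulk of the data under
heavy contamination that every point falls outside the biweight
support and the fit collapses; the high-breakdown start removes that
failure mode. Fits on fewer than 10 usable samples (~5 mm of branch)
or with a non-positive intercept are rejected and the branch carries a
missing value with a logged reason — never a silent drop. Both
thresholds are configurable.

**Inter-branch tapering (interBT).** Across one bifurcation,

    interBT = (d_p − d) / d_p × 100    [%]

with *d* the arithmetic mean of the branch's resampled diameters and
*d_p* that of its parent. The raw sample mean is used rather than a
fit-smoothed value: "average diameter" is read literally, and the
statistic is then entirely independent of the line-fit stage. interBT
may be negative (child wider than parent) and is undefined for the
root.

Both indices come in an *inner* (lumen) and *outer* (lumen + wall)
variant, computed independently.

**Airway–artery ratio (AA ratio).** For a matched airway/artery branch
pair, the artery profile is mapped onto the airway arc by
nearest-point correspondence and a 2-mm window slides along the branch
in 0.5-mm steps; the window minimizing the mean absolute difference
between outer airway and artery diameter is the measurement site, and
the ratios are mean inner (or outer) airway diameter over mean artery
diameter in that window. The 2-mm default trades locality against
stability (5 samples); it is configurable. One ratio is reported per
pair.

**Lung-volume normalization.** Every length of a subject (positions,
arc lengths, diameters) is multiplied by *(4 L / lung volume)^(1/3)*,
normalizing subjects to a 4-L lung. Under this map interBT and AA
ratios are exactly invariant and intraBT transforms as intraBT/s — the
test suite verifies both laws to 1e-9. Exact AA invariance requires
the measurement window to correspond across scales (a physical length
scales with the subject); with a window held fixed at 2 mm the
re-selected site can differ by a sample, bounding the discrepancy by
discretization, not by the ratio itself.

## Airway–artery pairing

Branch pairs are scored by

    cost = w_d · distance + w_a · angle + w_s · size

with distance the symmetrized mean closest-point distance between the
centerlines (mm), angle the unsigned angle between principal
directions (radians, from the first principal component of each point
cloud), and size the relative difference between mean artery diameter
and mean airway outer diameter. Defaults w = (1, 1, 2), acceptance
threshold 6. A one-to-one assignment minimizing total cost over
admissible candidates is computed with the Hungarian algorithm; a tiny
index-ordered perturbation (1e-10) makes tie-breaking lexicographic
and deterministic. The weights are a design choice validated by the
generator-correspondence property (≥95% of synthetic airway branches
pair with their generating companion) and by brute-force equivalence
on small instances.

## Cohort statistics

Branches are stratified into small/medium/large airways by the
accompanying-artery diameter, with cut points at the 33.33rd and
66.67th percentiles (linear interpolation) of artery diameters pooled
over the reference cohort's paired branches — three equally sized
groups on that cohort, transferable to others as a pure function of
diameter. The per-subject median summarises each biomarker (robust to
residual outliers); groups are compared with the two-sided
Mann–Whitney U test, enumerated exactly when the combined sample size
is ≤ 12 with no ties and otherwise by the normal approximation with
tie and continuity corrections. Spearman's rank correlation relates
per-subject medians to the visual severity score. No multiplicity
adjustment is applied by default (a Holm option exists). Subjects, not
branches, are the unit of inference.

## Synthetic cohorts

The generator builds binary bifurcating trees. Per branch the inner
diameter decays linearly, d(x) = d0·(1 − t/100·x), with the true
intra-branch tapering t drawn from a normal truncated to (−1, 5) %/mm;
outer = inner × 1.3 (constant wall fraction, so the outer taper equals
the inner in truth). Across each bifurcation the true inter-branch
tapering b is drawn from a normal truncated to (5, 60)% and the
child's proximal diameter is solved so that the child's *sample-mean*
diameter sits exactly b% below the parent's — b is then precisely the
quantity the interBT estimator targets, which is what makes the
noise-free pipeline recover every drawn t and b to machine precision.
Branch lengths are three diameters, rounded to whole 0.5-mm steps so
that the sample mean of a linear profile equals its analytic mean.
Branching angles are 35 ± 10°, with the bifurcation plane rotating
~90° per generation.

Companion arteries copy the airway topology, offset by 2 mm along a
subject-constant direction, carrying a single diameter. The artery
calibre follows the *healthy-reference* cascade at its tree position:
the subject's own tapering draws shifted by the gap between the
healthy reference (1.56 %/mm intra, 38.5% inter — the control means)
and the phenotype means, scaled by (1/1.16) × N(1, 0.05) relative to
the reference outer diameter. For a control subject that gap is zero,
so arteries mirror their airways and the outer AA ratio sits tightly
near 1.16; for the disease phenotype the arteries keep tapering at the
healthy rate while the airway does not, so the AA ratio rises towards
the periphery. Sharing the subject's draws (rather than using a fixed
deterministic reference) keeps a healthy subject's anatomical
variation out of the AA ratio, mirroring the fact that airway and
artery calibres co-vary in healthy anatomy. Because the synthetic
disease reduces tapering uniformly at *every* bifurcation, the
compounded AA elevation in deep generations is stronger than clinical
cohorts typically show; the direction and the periphery-dominant
pattern are the modelled features.

Phenotype means are taken from the matched-cohort medians the
biomarkers are designed to separate: control intraBT 1.56 %/mm and
interBT 38.5%; bronchiectasis 0.89 %/mm and 32.3%. Reduced tapering is
applied uniformly across the tree (not focally). Each subject draws
its own mean tapering around the phenotype mean (between-subject SD
0.25 %/mm intra, 3.0% inter, matching the reported inter-quartile
spreads) and branches scatter around the subject mean (SD 0.35 %/mm
and 6.0%); these within/between splits are calibration choices, not
reported quantities. Measurement noise is Gaussian (SD 0.05 mm),
applied to the lumen and the wall thickness separately so measured
outer ≥ inner always; with probability 0.02 a sample's whole
cross-section is multiplied by U(1.5, 3), mimicking a segmentation
leak. Lung volume is N(4, 0.6) L truncated to [1, 9]; the tree is
built at the 4-L reference scale and then scaled by (V/4)^(1/3), so
ground truth states tapering *after* normalization. The synthetic
visual score tracks the subject's loss of intra-branch tapering
relative to the 1.56 control reference plus noise, clipped to
[0, 100] — enough structure for the correlation stage, with control
medians near 0 and disease medians near 13.

What the generator does **not** emulate: CT intensities, partial
volume and reconstruction-kernel effects, focal/varicose/cystic
morphologies, mucus plugging, curved centerlines, or anatomically
asymmetric branching. Passing tests therefore demonstrate correctness
of the estimators and pipeline under the stated statistical structure,
not performance on clinical CT.

## Voxel phantoms and re-measurement

`rasterize_phantom` voxelizes a tree at isotropic spacing: a voxel is
foreground iff its centre projects onto a centerline segment within
the linearly interpolated local radius (flat-capped tubes, so a
straight cylinder's volume is πr²L). Lumen (label 2) overrides wall
(label 1). The spacing must be at most a quarter of the smallest
present diameter.

`PhantomMeasurer` re-measures diameters as twice the Euclidean
distance transform of the lumen (inner) or lumen + wall (outer) mask,
interpolated trilinearly at resampled centerline points — the largest
inscribed sphere centred on the centerline. This is a deliberately
simple, analytically testable surrogate for graph-based surface
measurement; its contract is the accuracy bound (cylinder error below
one voxel diagonal, decreasing with resolution), not the algorithm.
Samples nearer to a branch end than the local tube radius are
excluded: within roughly one radius of a bifurcation the inscribed
sphere leaks into the joining tubes (and near an open end it is
truncated), and the corruption length scale is the radius, not the
voxel. Trilinear interpolation of the distance transform gives a
small systematic underestimate (the field is sampled off-axis), which
cancels in slopes; the phantom-chain test budgets it.

## Problem sizes in the test suite

The acceptance-style checks run at desk scale: exactness chain on a
31-branch subject; phantom chain on three 7-branch subjects at 0.25 mm
(~14M voxels each); robustness on 200 simulated branches;
discriminative power on one hundred 12-vs-12 cohorts (the study's
group sizes) and null calibration on two hundred, with 63-branch
trees. All sizes are package defaults chosen to make the statistical
statements at the stated replicate counts.

## Known limitations

- The diameter surrogate underestimates diameters by a sub-voxel
  amount; absolute AA ratios from phantoms inherit this bias even
  though tapering slopes largely do not.
- The pairing cost and threshold are validated on synthetic companion
  geometry only.
- interBT from raw means is sensitive to unflagged outlier samples in
  a branch (robustness there comes from the per-subject median, as in
  the analysis design, not from the mean itself).
- Percentile conventions for the size tertiles are fixed (linear
  interpolation) but other conventions would shift thresholds slightly
  on small cohorts.
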
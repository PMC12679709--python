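# Methods

## Lesion network mapping

A focal brain lesion disrupts not just the tissue it destroys but the
distributed network that tissue participates in. Lesion network mapping
(LNM) estimates that network without patient functional imaging: the lesion
mask is used as a seed in a *normative connectome* — resting-state fMRI from
a large healthy cohort — and the typical functional connections of the
lesioned location are mapped across the whole brain.

For lesion $\ell$ and subject $s$ with in-brain time series
$x_{s,v}(t)$:

1. **Seed time course**: $\bar{x}_{s,\ell}(t)$, the unweighted mean of
   $x_{s,v}(t)$ over lesion voxels $v \in \ell$ that fall inside the brain
   mask.
2. **Correlation map**: Pearson $r_{s,v} = \mathrm{corr}(\bar{x}_{s,\ell},
   x_{s,v})$ for every in-mask voxel $v$.
3. **Fisher transform**: $z_{s,v} = \operatorname{atanh}(r_{s,v})$, with $r$
   clamped to $\pm(1 - 10^{-7})$ so the transform stays finite; this
   variance-stabilizes $r$ for across-subject statistics.
4. **Group map**: per voxel, the across-subject mean $\bar{z}_v$ and the
   one-sample T-score $T_v = \bar{z}_v / (s_v/\sqrt{N})$ with sample
   standard deviation $s_v$ (ddof 1) and $df = N - 1$.

Statistics are computed on Fisher-z maps throughout; a mean-r display map is
recoverable as $\tanh(\bar z_v)$. Lesion voxels are *not* excluded from the
output map — strong connectivity near the seed is expected and reported.
Zero-variance voxels (constant or masked-out series) define $r = 0$ rather
than propagating NaN; a voxel whose across-subject z values are identical
and nonzero receives $T = \mathrm{sign} \times 10^6$ with a logged warning
rather than infinity.

## Overlap maps

Each lesion's T map is binarized at a stringent symmetric threshold
($T > +\theta$ and $T < -\theta$, strict inequalities, default $\theta = 7$),
and the binary maps are summed across lesions per tail. For a 1000-subject
connectome ($df = 999$) and the 228,483-voxel MNI152 2mm brain mask,
$\theta = 7$ corresponds to a per-tail Bonferroni familywise bound
$228{,}483 \cdot P(T_{999} > 7) \approx 5.4\times10^{-7} < 10^{-6}$. The
positive and negative tails are thresholded and counted separately and
never mixed, which is why the per-tail (one-sided) bound is the relevant
one; the two-sided bound at the same threshold is about $1.07\times10^{-6}$.
For synthetic cohorts with a different $df$ and mask size, the threshold is
rescaled by inverting the same bound
(`overlap.smallest_equivalent_threshold`).

Peaks are reported for voxels reached by at least a fraction $f$ of the
cohort (default 0.9), with required count $\lceil f n \rceil$ and percent
reported with round-half-up (so 55/61 prints 90 and 25/28 prints 89; 30/33
prints 91 under this rule).

## Permutation inference

**One-sample (sensitivity).** The observation unit is the lesion: its
across-subject mean-z map. Under the null of symmetric errors around zero,
each lesion's whole map may be negated; the null distribution is built from
random sign flips (default 2000), or from exhaustive enumeration of all
$2^n$ assignments whenever that is within the permutation budget — in which
case the p-values are exact and the observed statistic is computed through
the same code path as the null so the identity assignment ties with the
observation exactly.

**FWE correction.** Per permutation the maximum statistic over in-mask
voxels is recorded (max $|t|$, max $t$, and min $t$, giving two-sided and
per-tail maps); the corrected p of a voxel is the rank of its observed
statistic in that max-null distribution. Monte-Carlo p-values use the
Phipson–Smyth correction $p = (1 + b)/(1 + B)$ and are never exactly zero.
A conservative step-down pass enforces that a voxel with a larger statistic
never receives a larger p. This is strong FWE control at the voxel level; no
cluster-extent inference or smoothing is performed.

**Two-sample (specificity).** The symptom cohort is contrasted against a
library of comparison lesions grouped into syndromes. The statistic is a
weighted Welch (unequal-variance) t with *reliability* weights: every
sensory case has weight 1, and each comparison syndrome $k$ of size $n_k$
among $K$ syndromes receives per-case weight $W/(K n_k)$ with $W$ the
sensory group's total, so every syndrome contributes equal total weight and
a large syndrome cannot dominate. Effective group sizes use
$n_\mathrm{eff} = (\sum w)^2 / \sum w^2$. The null permutes exchangeable
*blocks* between groups — each syndrome one block, each sensory lesion its
own block — preserving within-syndrome correlation; weights are recomputed
for each permuted partition under the same equal-block rule. Free (case
level) permutation is available as an option.

**Generalized Pareto tail approximation.** At 2000 permutations the
smallest resolvable empirical p is $1/2001$. When an empirical p falls
below the trigger (default 0.075), a generalized Pareto distribution is
fitted by maximum likelihood to the exceedances above the upper
`gpd_tail_fraction` (default 0.10) of the max-statistic null, with the
threshold placed halfway between the bounding order statistics. The fit is
gated by the Anderson–Darling statistic against the Choulakian–Stephens
critical values for the both-parameters-estimated case (interpolated over
the shape parameter, column chosen by `gof_alpha`); on failure the tail is
shrunk by 10 samples and refitted, and if no acceptable fit remains (or the
tail is degenerate) the empirical p is returned unchanged. Approximated
p-values are floored at machine epsilon and never exceed the empirical p.
Tail approximation is skipped for exhaustive runs, whose p-values are
already exact.

## Conjunction and parcellation coverage

Conjunctions are voxel-wise products of binarized FWE-significant masks,
taken per tail (positive with positive, negative with negative); the
within-cohort conjunction intersects the one-sample and two-sample results
("sensitive and specific"), and the cross-cohort conjunction intersects two
cohorts' one-sample maps binarized at the same FWE alpha (0.05 by default,
matching the primary tests). Coverage reports, per named atlas parcel, the
fraction of its voxels inside a significant mask; the atlas is
nearest-neighbour resampled onto the analysis grid first. Region tables
look up named world-mm coordinates, expanding "±x" into both hemispheres.

## Synthetic data

The generator plants a small number of spatially disjoint networks, each a
set of spherical nodes; per subject each network draws an i.i.d. standard
normal latent time course and a member voxel's signal is
$a L_k(t) + \varepsilon$, $\varepsilon \sim N(0, \sigma^2)$. Two
same-network voxels then have population correlation
$r = a^2/(a^2 + \sigma^2)$ — the closed form used as an oracle — and
cross-network voxels are independent. Defaults: 20 subjects, 100
timepoints, a 24³ grid (2 mm voxels) with a spherical brain mask of ~4800
voxels, 3 networks × 3 nodes, $a = \sigma = 1$, chosen so the full pipeline
runs in under a second per cohort while all statistical behaviours
(max-stat FWE, exhaustive vs Monte-Carlo, overlap peaks) are exercised at
realistic effect sizes; the 1000-subject scale of real normative connectomes
is a parameter, not a design constraint. Lesions are solid spheres (default
radius 1.6 voxels) either centred with jitter inside nodes of a target
network ("hits") or placed in background tissue away from every node; lesion
size is a free default, as real cohorts do not constrain it here. Cohort
metadata assigns modality ∈ {auditory, somatosensory} and direction ∈
{increase, decrease}, with the auditory-increase cell empty by default
(mirroring the real cohort composition). A null cohort forces every loading
to zero so any downstream detection is a false positive.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation, motion and physiological artifacts, spatial smoothness of
real fMRI noise, and inter-subject anatomical variability. Passing tests
therefore demonstrate the correctness and calibration of the *statistical
machinery* under the stated model, not performance on real data.

## Numerical choices

- Out-of-mask voxels carry exactly 0 with an explicit defined-mask, never
  NaN, so all reductions are finite.
- Binarization cutoff for traced masks defaults to 0.5 (handles 0/1 and
  0/255 dialects); nearest-neighbour interpolation for all masks and label
  volumes preserves binary semantics.
- Overlap peak components are 26-connected; ties at the component maximum
  break to the smallest lexicographic voxel index.
- `significant_mask` uses strict `p < alpha`; `alpha = 1` means "all tested
  voxels".
- One run seed fans out to per-stage seeds via a hash of the stage name, so
  any stage can be reproduced in isolation; permutation metadata (seed,
  permutation count, exhaustive flag) is persisted in JSON sidecars.

## Problem sizes used in the validation suite

Familywise error calibration uses 200 independent null cohorts at the
default generator scale; planted-network recovery uses 100 replicates; the
Monte-Carlo-vs-exhaustive comparison uses 12 lesions on a 20-voxel mask
(4096 enumerable assignments); the closed-form correlation check uses 2000
timepoints; the GPD accuracy check aggregates 25 draws of 2000 null samples
with a geometric mean, because a single 2000-sample tail extrapolation to
p = 0.001 has a sampling spread wider than a factor of two even when the
method is exact — the geometric mean isolates the method's bias from that
draw noise.

## Known limitations

- The two-sample permutation recomputes syndrome weights per permuted
  partition; alternative conventions (freezing observed weights) exist and
  would change p-values slightly. Block permutation is the default because
  it preserves within-syndrome dependence under the null.
- The Welch statistic with reliability weights is one of several reasonable
  weighted two-sample statistics; permutation inference makes the p-values
  valid regardless, but the statistic choice affects power.
- GPD tail p-values below ~1e-6 from 2000 permutations are extrapolations;
  they are reported but should be read as orders of magnitude.
- Whether across-subject statistics should average r or z is a genuine
  degree of freedom in the field; this package standardizes on z.
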
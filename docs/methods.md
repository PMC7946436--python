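# Methods notes

This document records what each stage computes, the assumptions behind
the synthetic generator, the defaults that matter, and the numerical
choices made where the design was genuinely open.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic data: what it emulates and what it does not

The generator emulates the *outputs* of a three-task event-related fMRI
experiment at the level the analyses consume — it does not simulate BOLD
time series, hemodynamics, or realistic fMRI noise spectra.

**Trial design.** Each run contains 40 attentional-reorienting trials
(8 *invalid* / 30 *valid* / 2 *catch*), 40 lexical-decision trials
(20 *word* / 20 *pseudoword*), and 6 perspective-taking trials
(3 *false belief* / 3 *true belief*); subjects complete three sessions of
four runs.  Trial order is pseudo-randomized per run.  Onsets are simple
jittered sequences (mean ITI 3.8 s, SD 1.7 s, floor 2 s) carried for
completeness; no downstream stage consumes timing.  Response correctness
is Bernoulli with per-condition accuracy 0.95 (catch trials have
undefined correctness), so the "correct trials only" filters are
genuinely exercised.

**Voxel activity.** A trial's beta at a voxel is
`baseline + subject offset + planted effect + N(0, noise_sd)` with
i.i.d. Gaussian noise across voxels and trials — no spatial
autocorrelation, which keeps the sampling-theory oracles in the tests
analytic.  The planted specialization pattern mirrors the qualitative
task-specific layout the pipeline is meant to detect: the attention
target condition drives the right **anterior** subregion, the semantic
target the left **anterior** subregion, and the social target both
**posterior** subregions; control conditions carry no effect.  Defaults:
effect 1.0, noise_sd 1.0, subject_sd 0.5, baseline 0 (beta units).  The
paper-scale experiment reports no effect magnitudes, so these are
qualitative study conditions, not estimates of real data; passing tests
show the pipeline recovers structure of this kind, not that real IPL data
contain it at these magnitudes.  An optional `boundary_taper` blends the
anterior/posterior effects smoothly across the planted boundary, creating
genuinely ambiguous border voxels (used to show that consensus-unstable
voxels concentrate at the boundary).

**ROI grids.** Each hemisphere is a rectangular voxel grid (default
10×11×10 ≈ the ~1100-voxel scale of a real IPL mask; tests use a few
hundred voxels).  The planted anterior/posterior boundary is a plane
perpendicular to the second grid axis at `(1 − anterior_fraction)·ny`
(continuous voxel units); a voxel is anterior iff its center lies
anterior of the plane.  Hemisphere affines are mirror images across
x = 0, so flipping the first grid axis realizes the left–right mirror.
Arbitrary NIfTI masks load through `io.mask_from_nifti`.

**Parcel series and modulations.** A planted coupling
(task, subregion, parcel set, ρ) sets, on that task's trials,
`parcel = ρ·z(subregion) + sqrt(1−ρ²)·noise`; everything else is
standard-normal noise.  Subject-wise 4×4 modulation matrices are
`truth(task) + N(0, subject_sd)`; the default truth plants a sparse
pattern of facilitatory/inhibitory directed links.

## Parcellation

Features: one column per (subject, task) — the mean beta over the
subject's correct target-condition trials minus the rest baseline (zero
in the synthetic setting), pooled across subjects; one row per voxel.

The k-means ensemble advances all random initializations simultaneously
(vectorized Lloyd iterations, squared-Euclidean distance, initial
centroids drawn as k distinct data points per member, convergence when
the maximal centroid movement falls below 1e-6 or at 300 iterations;
empty clusters retain their previous centroid).  Default 1000 members per
k; the consensus needs every member's labels, which is why the ensemble
is explicit rather than a best-of-n fit.

**Validity vote.** Twelve indices are computed on each k's best
(lowest-WCSS) partition over k = 2..7.  Max-rule: Calinski–Harabasz,
silhouette, Dunn, point-biserial, PBM, Ratkowsky–Lance; min-rule:
Davies–Bouldin, C-index, McClain–Rao, Xie–Beni.  Hartigan uses
H(k) = (W_k/W_{k+1} − 1)(n − k − 1) and votes the smallest k with
H ≤ 10, falling back to the largest drop; Krzanowski–Lai votes the k
maximizing |DIFF(k)|/|DIFF(k+1)| with DIFF(k) = (k−1)^{2/p}W_{k−1} −
k^{2/p}W_k.  The successive-k indices need W at k = 1 (computed
analytically) and k = k_max+1 (an extra ensemble).  An index undefined on
some partition abstains and is logged.  Two caveats observed on clean
two-cluster toys: McClain–Rao's min rule is biased toward the largest
candidate k (its ratio decreases as clusters fragment), and Hartigan's
threshold rule is sample-size sensitive; both are retained with their
stated rules, and the *majority* vote is what the pipeline endorses.
Agreement is reported as the share of non-abstaining indices voting for
the winner; ties break toward smaller k.

**Consensus.** Every member is aligned to the reference member (lowest
WCSS) by maximum-overlap one-to-one label matching (Hungarian algorithm
on the label confusion matrix).  The consensus label is the modal aligned
label; a voxel is *stable* iff that label occurs in at least
`stability_threshold` (default 1.0 — strict unanimity, configurable) of
the members.  Unstable voxels carry no subregion membership downstream.
Note the alignment-invariance property (relabeling a member never changes
the consensus) holds when the optimal matching is unique; for degenerate
ensembles with tied confusion matrices the matching, and hence the
consensus, is only defined up to those ties.

**Naming and congruency.** With k = 2 the cluster whose stable-voxel
center of mass lies more anterior (+y via the mask affine) is "anterior";
for k > 2 names are ordinal along the axis.  Congruency flips one
hemisphere's label volume across the first grid axis and reports, per
hemisphere, the % of ROI voxels present in both masks, plus per-subregion
(and overall) label concordance over the shared stably-labeled voxels;
concordance is reported as undefined when no voxels are shared.

## Decoding

Only correct target-condition trials (invalid, word, false belief) enter.
Per LOSO fold: (1) **balance** — within each (subject, session, run),
every task is subsampled without replacement to the run's minimum
per-task count (with the printed design and the 0.95 accuracy this is
usually the social count, ~3); a run whose minimum is zero contributes
nothing and is logged, rather than aborting, since the correct-only
filter makes empty cells possible; (2) **deconfound** — subject identity
by within-subject mean-centering from each subject's own rows (indicator
regression is impossible under LOSO because the held-out subject is
unseen; centering is the leakage-free equivalent), then session number,
session time, and run time regressed out by least squares fitted on
training rows only and applied to test rows (zero-variance columns
dropped and logged); (3) **standardize** — per run and column to mean 0,
variance 1 with the population (n) convention, making the (1,3) → (−1,1)
contract exact; a zero-variance column within a run is set to 0;
(4) three one-vs-rest logistic discriminants (L2, C = 1.0 — the
regularization is a package default, chosen as the standard convex
baseline; configurable) fitted on training subjects; held-out trials are
predicted by the maximal decision value, ties broken by the fixed task
order attention < semantics < social and logged.  The signature is the
exact mean of per-fold weight vectors (per-fold values are retained on
the object).

## Connectivity shifts

Per task, Pearson r between each subregion's and each parcel's beta
series over that task's correct target trials (minimum 5); Fisher
z = atanh(r) with r clipped to ±(1 − 1e-7) so z stays finite; constant
series yield missing cells.  The shift statistic is z(task) minus the
across-task mean of z.  The pooled baseline permutes task labels across
trials — within subject by default, preserving per-task counts; a pooled
(across-subject) shuffle sits behind `strategy=` since the original
procedure's shuffling unit is not fully determined — and recomputes the
statistic (default 5000 permutations).  Two-tailed empirical p-values use
the add-one convention p = (1 + #{|null| ≥ |obs|})/(1 + n_perm); a cell
is flagged at p < α (default 0.05) with **no** correction across parcels
by default, mirroring the per-cell threshold reading; Benjamini–Hochberg
at FDR α is available via `correction="bh"` and is what the planted
recovery test uses, since at hundreds of parcels an uncorrected 5%
threshold necessarily dilutes precision.

## Directed-modulation test

For task t and connection (a→b): statistic = mean over subjects of
(B_t[a,b] − mean of B of the other two tasks); self-connections excluded
by default.  The null permutes the three task assignments independently
within each subject (default) or sign-flips subject-wise contrasts
(`strategy="sign_flip"`); both respect subject exchangeability.  A
connection is flagged when |observed| exceeds the 99.9th percentile of
its |null| (default 10,000 permutations; at least ⌈100/(100−q)⌉ are
required).  Note the percentile rule's exact exceedance probability under
the null is (m+1−k)/(m+1) with k the interpolated order statistic —
about 0.0011 at m = 10,000 but about 0.002 at the minimum m = 1000 — so
the add-one empirical p-value is always reported alongside, letting users
apply either decision rule.  The group mean strength per task accompanies
every flagged connection.

## Pipeline and reproducibility

`validate_config` fills documented defaults (n_init 1000, k range 2..7,
α 0.05, connectivity permutations 5000, EC permutations 10,000 at the
99.9th percentile) and rejects contradictions naming the field.  One
global seed expands into per-stage seeds via `numpy.random.SeedSequence`
spawning, so each stage is independently reproducible; the manifest
stores the config hash, seeds, stage wall times, and package version.
Identical config + seed gives byte-identical text outputs.

## Problem sizes used in the shipped checks

The shipped tests and the acceptance script run at desk scale, chosen as
the package's own defaults for fast, deterministic verification: ROI
grids of 200–500 voxels per hemisphere, 4–20 subjects, ensemble sizes of
30–200 members (the recovery check uses 100 members across 20 generator
seeds), 150–2000 connectivity permutations, 1000–5000 EC permutations,
and 200-replicate calibration simulations.  The chance-level calibration
uses the full design (20 subjects × 12 runs) with zero planted effects.
These sizes do not change any algorithmic defaults, which remain at the
full-scale values above.

## Known limitations

* The voxel noise model is i.i.d. Gaussian; real beta series carry
  spatial and temporal structure that would loosen the stability and
  calibration margins observed on synthetic data.
* The validity battery is a fixed, documented set of 12 indices; vote
  agreement percentages are therefore not comparable to batteries of a
  different size or composition.
* Modulation matrices are consumed, never estimated: no DCM inversion,
  Bayesian model selection, or parameter averaging is performed.
* With k > 2 the anterior/posterior naming degenerates to ordinal
  segment labels; the congruency report is defined for the two-cluster
  naming only.
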
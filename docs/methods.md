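# Methods

## Pipeline

Every subject's analysis is the same five-stage chain, applied once per
smoothing level:

1. **Smoothing** (`smoothing`). The voxel series are convolved with an
   isotropic Gaussian parameterized by FWHM in mm, σ = FWHM/(2√(2 ln 2)),
   sampled at voxel offsets in mm space (anisotropic voxels are handled by
   evaluating the Gaussian at physical offsets) and truncated where any axis
   offset exceeds 4σ (truncated weights are < 3.4e-4 of the center weight).
   The output at voxel *i* is Σ G_i(j)x_j / Σ G_i(j). FWHM 0 is the exact
   identity and serves as the unsmoothed baseline.
2. **Aggregation** (`parcellate`). ROI series are unweighted means of member
   voxel series; ROI centroids are unweighted means of member voxel centers,
   with voxel centers at (index + 0.5)·voxel_size. Link length is the
   Euclidean centroid distance.
3. **Network construction** (`network`). Link weights are pairwise Pearson
   correlations with zero diagonal. Thresholding to density d keeps exactly
   round-half-up(d·R(R−1)/2) top-weighted pairs as an unweighted graph:
   456 links at d = 10% and 137 at d = 3% for R = 96.
4. **Node metrics** (`metrics`). Degree; competition degree ranks
   (descending, ties share the minimal rank); eigenvector centrality by
   power iteration v ← Av/|Av|₂ from a uniform positive start. LCC by
   connected-component enumeration. Cross-subject consistency as LCC
   membership fractions and link prevalence.
5. **Cohort comparisons** (`pipeline`). Per FWHM level versus the baseline:
   degree change (plain cross-subject mean degrees), rank change (ranks of
   mean degrees, so one rank map per level), eigenvector change, per-pair
   Fisher-Z weight change binned by link length, the Pearson correlation of
   ROI size with degree change, and the LCC-membership dispersion
   mean(p(1−p)).

Correlation averaging across subjects and correlation differences are done
on the Fisher-Z scale (Z = arctanh r), which reduces averaging bias;
correlations are clipped at |r| = 1−1e−7 before the transform because
noise-free synthetic data can produce exact ±1.

## Boundary handling in smoothing

The normalization sum at the brain edge is ambiguous in volumetric
pipelines, so two policies are implemented. The default,
`mask_renormalized`, restricts numerator and denominator to in-mask voxels,
which preserves constant fields exactly and does not attenuate edge signal.
`unmasked` zero-pads outside the mask and divides by the full kernel sum
(edge attenuation, exactly separable). Both are evaluated as the identical
truncated-kernel sums; the implementation computes them by FFT convolution
of the numerator and denominator fields, which agrees with direct
brute-force evaluation of the sums to ≈1e−13 (asserted at 1e−10 in tests).

## Eigenvector centrality details

Power iteration uses tol 1e−10 on the L∞ change of successive unit
iterates and max_iter 1e5. On a graph whose largest connected component is
bipartite the iteration oscillates between the ±λ_max eigenspaces, so the
computation detects that case and solves the symmetric eigenproblem
directly, taking the sign-fixed leading eigenvector. Isolated nodes score
0. Degenerate leading eigenvalues across components (e.g., two identical
components) raise rather than silently picking a mixture.

## Synthetic cohort: what it emulates and what it does not

The generator's defaults define the study conditions: a 20×20×10 grid of
4×4×4 mm voxels (a scaled-down two-hemisphere volume; 4 mm matches common
downsampled acquisitions), 96 ROIs, log-normal size heterogeneity σ = 1.0
(chosen to match an anatomical parcellation whose sizes span 5–857 voxels
with median 88 and mean ≈ 1.6× the median), 13 subjects × 212 timepoints,
latent coupling scale λ = 30 mm, homotopic boost 0.25, voxel noise sd 1.0
(unit signal-to-noise), and subject perturbation sd 0.1 on the correlation
target. λ and the boost are free parameters — no published decay rate
exists to fit them — picked once to give short-range correlations ≈ 0.6
and long-range ≈ 0.05 before smoothing.

Construction: the left hemisphere is partitioned by seeded region growing
(farthest-point seed placement, 6-connectivity FIFO growth scheduled by the
smallest claimed/target fraction, log-normal integer targets by
largest-remainder apportionment) and mirrored to the right, so homotopic
pairs are exact mirror images. The latent ROI correlation target is
C = exp(−D/λ) plus the homotopic bonus, clipped off-diagonal and projected
to the nearest correlation matrix (eigenvalue clipping at 0, diagonal
rescaled to 1). Per subject the target is perturbed by a symmetric Gaussian
and re-projected; latent series are i.i.d. Gaussian in time (the analysis
is correlation-based and time-order-free, so no autocorrelation or
hemodynamics are modeled); voxels add independent Gaussian noise. Subject
*s* uses sub-seed `seed + 1000(s+1)`; identical seeds give bit-identical
cohorts.

Features of real data deliberately not emulated: hemodynamic response and
temporal autocorrelation, physiological and motion artifacts, scanner
drift, registration error, non-stationary noise, and anatomically
structured functional clusters. Consequently a passing suite shows that the
*mechanisms* of smoothing distortion (noise reduction favoring small ROIs,
cross-boundary signal mixing favoring short links) operate as described —
not that effect magnitudes on real data are reproduced; the headline
correlations measured here (e.g., size-vs-degree-change r ≈ −0.4…−0.5 at
seed 0) are cohort-specific. One real-data property the generator does not
reproduce at all is the sharpening of the degree distribution (rising
maximum, falling median) under smoothing: lacking spatially clustered hub
anatomy, the synthetic cohort instead homogenizes degrees slightly. The
LCC-dispersion reduction is likewise a trend with 13-subject sampling
noise: every smoothed level sits clearly below the unsmoothed baseline,
but adjacent kernel widths can swap order between seeds.

## Numerical and design choices

- Threshold ties at the cutoff weight are broken lexicographically by node
  pair; negative correlations compete on signed value (−0.9 is weaker than
  0.1). Both choices make networks bit-reproducible and edge counts exact.
- Degree summaries across subjects are plain means (degrees are counts, not
  correlations); ROI-ROI weights are Fisher-Z averaged.
- Rank changes are computed on cross-subject mean degrees, giving one rank
  map per smoothing level rather than noisier per-subject rank maps.
- Distance bins default to 10 mm, left-closed, starting at 0; empty bins
  are reported as missing, never as zero.
- The LCC-membership dispersion statistic mean(p(1−p)) is this package's
  own summary of inter-subject LCC variability (the effect it measures is
  usually shown visually); it is 0 when all subjects share an LCC node set
  and 0.25 at maximal disagreement.
- Degenerate inputs are rejected loudly: empty masks, constant ROI series
  (named), missing ROI ids, densities outside (0, 1], grids too small for
  the requested ROI count.

## Problem sizes

The default experiment (4000 voxels, 96 ROIs, 13 subjects, 212 timepoints,
4 smoothing levels) runs in well under a minute on one CPU; the Monte-Carlo
correlation checks use a single subject at 5000 timepoints. These sizes are
the package's study conditions and keep every property measurable at
interactive speed.
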
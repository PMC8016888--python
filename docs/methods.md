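# Methods

`netqual` studies a confound in graph-theoretical analysis (GTA) of
resting-state fMRI: group differences in network parameters can arise from
group differences in *fMRI signal quality* rather than from brain
organisation.  The package implements the complete analysis — quality
metrics, network construction, threshold sweep, permutation inference with
covariate residualization — together with a synthetic BOLD cohort generator
that encodes the mechanism explicitly, so the whole claim can be exercised
end to end on data whose ground truth is known.

## The mechanism

Pearson correlation between two noisy signals is attenuated by the noise.
For a pair

y_i(t) = m + a·(c·s(t) + u_i(t)) + ε_i(t),  i = 1, 2,

with s, u_i independent unit-variance band-limited Gaussian processes and
ε_i white noise of standard deviation σ, the population correlation is

ρ = c²a² / (a²(c² + 1) + σ²).

(The derivation is two lines: cov(y₁, y₂) = a²c², since only the shared
drive s is common, and var(y_i) = a²(c²+1) + σ².  With a private-drive
standard deviation u the denominator's `1` generalizes to u²; `u = 0`,
`σ = 0`, `c = 1` gives ρ = 1.)

At fixed σ, lowering the fluctuation amplitude `a` simultaneously

* lowers the contrast-to-noise ratio CNR = |max − mean| / σ_N,
* raises the temporal SNR tSNR = mean / sd (the fluctuation *is* the sd), and
* lowers every pairwise correlation — hence fewer supra-threshold edges,
  lower efficiency and clustering, longer paths.

A group whose BOLD amplitude is reduced therefore shows "altered network
topology" without any change in the underlying coupling.  The `simulation`
module demonstrates this on signal pairs; the `synthetic` + `workflows`
modules demonstrate it at cohort scale.

## Quality metrics

* **SNR** = mean brain intensity over voxels and frames / σ_N, where σ_N is
  the pooled standard deviation over all (air voxel, frame) samples; air
  voxels are those with air/background probability above 0.5.  SNR indexes
  scanning quality and is designed *not* to differ between synthetic groups.
* **tSNR** = temporal mean / temporal sd of a regional signal.
* **CNR** = |max − mean| of a regional signal / σ_N.

Conventions (all switchable): standard deviations are population (ddof 0);
the subject-level tSNR/CNR scalar is the unweighted mean over the 94
regional values (how a per-subject value is aggregated is not canonical; the
region mean is the least-structured choice and — because the ~94 regional
estimates average down measurement noise — gives the covariates used in the
quality-adjusted regression good reliability); quality is computed on the
pipeline's output signals (band-passed, temporal mean restored), with σ_N
from the raw trimmed volume.

## Signal pipeline

Fixed order: trim (10 head + 10 tail frames) → motion QC (exclude if any
frame moves strictly above 1 mm translation or 0.0125 rad rotation) →
regional mean extraction over the integer parcellation → nuisance regression
on the mean extracranial (air) time-series (OLS per region, temporal mean
restored afterwards so mean-based quality metrics stay defined) → band-pass
0.009–0.08 Hz.  The filter is a 4th-order Butterworth applied
forward-backward (zero phase), so it cannot shift signals relative to one
another and bias correlations.  Whether nuisance regression precedes or
follows filtering is not canonical; the order above is the default and both
steps are independently callable.  ALFF is the summed periodogram power in
0.01–0.08 Hz.

## Networks and graph parameters

The adjacency matrix is the 94×94 Pearson correlation matrix of the
processed regional signals (diagonal zeroed).  Binarization keeps edges with
r strictly greater than τ; negative correlations never form edges.  The
threshold grid runs from 0 in steps of 0.01 up to the largest value at which
*every* subject's network (both groups) is still connected, so all
comparisons see connected graphs on a shared grid.  A proportional
(fixed-density) extraction is provided as the alternative that equalizes
network size across subjects; ties break lexicographically so equal density
always means equal edge count.

Per binarized graph the package computes: number of edges, mean degree
2|E|/n, clustering coefficient (mean of per-node triangle density, 0 for
degree < 2), transitivity (3·triangles / connected triples), characteristic
path length (mean BFS distance over ordered pairs; requires connectivity),
global efficiency (mean 1/d, unreachable pairs contribute 0), local
efficiency (mean over nodes of the global efficiency of the neighbour
subgraph), and small-worldness σ = (C/C_rand)/(L/L_rand).

The σ reference is an ensemble of 20 Erdős–Rényi G(n, m) graphs with
matched node and edge counts, seeded deterministically per (subject,
threshold); C_rand and L_rand are ensemble means, with L_rand averaged over
reachable pairs if a sample is disconnected.  A degree-preserving null would
be stricter; ER is the cheap, common convention and the reference is
injectable (`gta_metrics(..., reference=...)`) for anyone who wants a
different null.  Distances use unweighted BFS realised as boolean matrix
products — exact, and fast for these small dense graphs.

## Statistics

* **Permutation tests**: statistic = difference of group means; labels
  shuffled preserving group sizes; two-sided; p = (1 + #{|perm| ≥ |obs|}) /
  (n_perm + 1), so p is never zero and the floor is 1/(n_perm+1).  One
  comparison call shares its permutation assignments across all (metric,
  threshold) cells, making the scan a single matrix product and the whole
  result reproducible from one seed.
* **Residualization**: pooled OLS of the metric on [intercept, covariates],
  residuals + grand mean.  Pooling across groups is the point: any group
  difference the covariates can explain is absorbed by the fit.
* **Covariate contribution**: permutation p for one covariate's coefficient
  (permute that column, refit, compare |β|), computed via
  Frisch–Waugh–Lovell partialling so the refits vectorize.
* **Cognition correlations**: Pearson r with t-distribution p per (GTA
  parameter, cognitive score, threshold); familywise correction by
  Dunn–Šidák, α_corr = 1 − (1 − α)^(1/m) with m = 7×7 = 49 pairs per
  threshold (whether thresholds multiply the family is ambiguous; the
  per-threshold family is the default and m is configurable).
* **Edgewise comparison**: permutation test per edge on Fisher-z transformed
  correlations (raw-r mode available), Cohen's d with pooled sd, plus the
  per-group overall mean FC.
* **Summary t-tests**: pooled-variance two-sample t from printed means/sds/ns
  (the pooled form reproduces the reference cohort table's CVLT-II and Age
  p-values, 0.007 and 0.28).

## Synthetic cohort generator

Regional signal for region i:

x_i(t) = m + a·( Σ_j C_ij·s_j(t) + u_i(t) ),

with one unit-variance band-limited (0.01–0.08 Hz) shared process s_j per
region, a private process u_i, and symmetric zero-diagonal loadings C.  The
latent processes are white noise filtered by the same Butterworth band-pass
the analysis uses (so generator and analysis agree on the spectrum) and
standardized to exact unit sample variance.  Every voxel of region i carries
x_i plus independent white scanner noise (sd σ); air voxels carry pure
scanner noise.  Consequences used throughout the tests:

* single-voxel tSNR = m / √(a²(ΣC_ij² + 1) + σ²) exactly;
* correlation between regions i and k grows with Σ_j C_ij·C_kj and is
  attenuated by the noise surviving regional averaging and filtering.

Note the zero diagonal means two regions correlate through *common* drive:
an isolated pair with a single nonzero loading has expected r = 0.

**Default study conditions.**  25 healthy-like subjects at amplitude 10 and
49 patient-like subjects at amplitude 8 (a 20 % reduction); baseline mean
1000, scanner noise sd 100, TR 3 s, 200 frames; volume 48×48×24 with a
10-voxel air margin (52 160 air voxels) and the 28×28×4 interior split into
94 equal contiguous regions of 33–34 voxels.  The latent network has 8
blocks with loading 0.30 inside and 0.07 between, giving within/between
block correlations of roughly 0.36/0.23 (healthy-like) before subject
noise.  The noise level was chosen analytically so that, after voxel
averaging (÷√33) and band-passing, residual noise variance is comparable to
the fluctuation variance — the regime in which the attenuation mechanism is
actually active (resulting in SNR ≈ 10, tSNR ≈ 53, mean FC ≈ 0.22 for the
healthy-like group).  Per-subject amplitudes get a lognormal multiplier
with unit mean and coefficient of variation 0.2, representing inter-subject
variability of BOLD amplitude; this keeps the group separation in tSNR/CNR
moderate rather than degenerate and gives the quality covariates genuine
within-group variance to regress on.  Demographics: age ~ Normal(44, 11)
truncated to [18, 65]; education ~ Normal(14.5, 2.6).  Cognition columns
are placeholders drawn from configurable per-group normals.  Motion traces
are small bounded random walks (the generator does not attempt realistic
head motion).

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: no haemodynamic response or vascular coupling
physiology, no spatial autocorrelation beyond region membership, no
registration/normalization artefacts, no lesions or atrophy, no realistic
motion, no physiological (cardiac/respiratory) noise, Gaussian statistics
throughout.  The cohort is a *mechanism demonstrator*: it shows that an
amplitude-only group difference reproduces the observed pattern (tSNR up,
CNR down, apparent GTA differences that vanish under quality covariates),
not that real patient data contain no genuine reorganisation.

## Numerical and design choices

* Motion thresholds are strict inequalities (a frame exactly at the limit
  passes).
* Frame trimming precedes motion QC; QC is evaluated on the trimmed range.
* Pearson matrices are symmetrized and clipped to [−1, 1] against rounding.
* Permutation p-value comparisons use a 1e-12 slack so exact ties (e.g. the
  all-equal case) count as exceedances.
* `gta_metrics` raises on disconnected graphs (path length undefined);
  `allow_disconnected=True` returns NaN path length/small-worldness while
  the efficiencies remain defined (unreachable pairs contribute 0).
* Threshold grids are rounded to the 0.01 step to avoid floating-point
  drift; the first disconnection is found by scanning the grid upward.
* Bandpass `padlen` is capped below the series length so short test signals
  remain filterable.

## Problem sizes

The default cohort analysis (74 subjects, ~20–40 grid thresholds, 20-graph
σ reference per threshold) runs in about two minutes on one core; the
permutation scans use n_perm = 1000 by default in the workflows (the
add-one p floor is then ~0.001), with n_perm = 10 000 available where
sharper p-values are wanted.  The type-I calibration uses 1000 null
cohorts of 25 + 49 at n_perm = 1000; the simulation grid uses 5 amplitudes
× 200 replicates × 200 frames.

## Known limitations

* The ER small-world reference is permissive; σ values should be compared
  only within an analysis, not across publications using rewiring nulls.
* Quality metrics are computed on regional (not voxel-wise grey-matter)
  signals; a voxel-wise tSNR map export exists but its anatomical
  interpretation is out of scope.
* The equal-network-size (proportional) extraction is provided but the
  threshold-sweep analysis is the primary path.
* With only two groups and amplitude as the single manipulated factor, the
  cohort cannot probe interactions (e.g. amplitude × motion).
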
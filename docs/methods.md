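# Methods

## The model

`connctl` treats a subject's task-state functional connectome as the
coupling of a noise-free discrete-time linear system

    x(t+1) = A x(t) + B u(t),        A = M / (1 + σ_max(M)),

where `M` is the Fisher-z Pearson correlation matrix over the 80
concatenated task volumes (4 blocks × 20 volumes per working-memory load)
with zeroed diagonal, and `σ_max` its largest singular value.  For
symmetric `M` this normalization guarantees spectral radius < 1, so the
infinite-horizon controllability Gramian of every single-node input
`B = e_i` exists.

Two node-level metrics are computed per subject and load:

* **Average controllability** — `ac_i = trace(W_i)` with
  `A W_i Aᵀ − W_i + e_i e_iᵀ = 0`; for symmetric `A` this is the i-th
  diagonal entry of `(I − A²)⁻¹`.  `ac_i ≥ 1` always, with equality iff
  node *i* is decoupled.
* **Modal controllability** — `φ_i = Σ_j (1 − λ_j²) v_ij²` over the
  eigenmodes `(λ_j, v_j)` of `A`; `0 < φ_i ≤ 1` for stable symmetric `A`.
  Nodes participating mainly in strongly damped modes (high `φ`) can push
  the system toward difficult-to-reach states.

Three independent routes to `ac` (closed form, per-node discrete Lyapunov
solve, truncated Gramian sum) are kept in the package and pinned against
each other at 1e-8 in the validation suite.

Nodewise group inference is an analysis of covariance: a linear model with
intercept, covariates (sex, age, education, mean framewise displacement)
and diagnosis dummies; the omnibus group effect is the extra-sum-of-squares
F (3 numerator df for four groups).  Benjamini–Hochberg FDR is applied
across the 264 nodes separately within each metric × load family (four
families).  Post hoc contrasts are the six pairwise adjusted mean
differences from the same model, FDR-adjusted within each detected node by
default (`pooled` available).  Clinical and cognitive relations are Pearson
partial correlations after residualizing both variables on the covariates;
clinical scales are evaluated over the patients carrying the scale, task
performance over all participants.

Spatial association correlates a signed abnormality map — `sign(adjusted
HC mean − adjusted patient mean) · √F` per node, over all nodes — with each
annotation map, with two-sided add-one permutation p-values
(`p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + n_perm)`, default 5,000
permutations) from either label shuffling or autocorrelation-preserving
surrogates (shuffled values re-smoothed with a Gaussian kernel whose scale
is fitted to the map's empirical correlogram), and BH-FDR across maps.
Regional differential expression contrasts mean expression inside a region
against all remaining nodes, with a null built from random node sets of
matched size (minimum region size 5; a region covering the whole
parcellation is rejected since no background remains).

## The synthetic study

No subject-level data are distributable, so every stage runs against a
synthetic cohort with known ground truth.

**Cohort.**  Four groups (SZ 105, BD 67, MDD 51, HC 80; 303 total by
default).  Demographics, clinical scales (BPRS, SAPS, SANS, YMRS, HAMD,
HAMA), medication equivalents and n-back performance are truncated normal
draws parameterized by the published group means and SDs, with the
published availability pattern (e.g., mania/depression scales only in BD
and MDD).  Sex is Bernoulli with the published male fraction.  Head motion
is not published and uses plausible values (patients ≳ controls,
0.12–0.18 mm mean FD).  Ages are truncated to the study's 18–50 inclusion
range, accuracies to [0, 1].  A latent per-subject severity (standard
normal, truncated at ±2.5) modulates the injected coupling effects;
selected scores (BPRS ρ = 0.5, task accuracies ρ = −0.4) are rank-matched
within group to a noisy copy of severity via a Gaussian copula, so
score–controllability correlations are recoverable by construction.

**Dynamics.**  A subject's coupling is `A = M + g gᵀ` (zero diagonal):
`M` a modular within-network-dominant symmetric matrix (spectral radius
0.35) and `g` the nonnegative loadings of a dominant global coherent mode
(‖g‖² = 0.6).  Block time series follow the stable recursion
`x(t+1) = A x(t) + ε`, each of the four blocks initialized independently
from the exact stationary distribution.  Innovation scale is irrelevant to
the connectome (correlations are scale-free); no hemodynamic convolution
is applied — connectome construction, not BOLD realism, is the test
surface.

**Injected effects.**  Modal-controllability deficits *redistribute*
global-mode loading toward the affected nodes at conserved total norm
(default gains SZ 3.0, BD = MDD 2.0 on roughly half of the frontoparietal
nodes, high load only), so the affected nodes participate more strongly in
the weakly damped global mode while total coupling strength stays
group-stable.  Average-controllability deficits attenuate the node's
modular rows (default gain 0.3; visual nodes for SZ and MDD and one
frontoparietal node for SZ at high load, one memory-retrieval node for SZ
at low load).  Applying the controllability metrics to the group coupling
templates themselves reproduces the intended ordering (SZ < BD ≈ MDD < HC
on affected-node modal controllability), which the test suite asserts.

The redistribution design is deliberate.  A naive per-node coupling boost
does *not* survive the estimation path: it inflates the subject's σ_max,
and the global `1/(1 + σ_max)` normalization then reverses the local
effect in finite samples even though the infinite-data limit is correct.
Conversely, perturbations that change total coupling strength leak a
cortex-wide shift through the same normalization.  Redistribution at
conserved norm threads this needle and yields recoverable, correctly
ordered deficits.

**Annotation maps and expression.**  Annotation maps are Gaussian-kernel
smoothed white-noise fields over the node coordinates (nine tracer-family
names); when a target pattern and ρ are requested, the field is
orthogonalized against the target and recombined so the realized in-sample
correlation equals ρ exactly.  Expression is gene-specific baseline +
smoothed spatial field + i.i.d. noise, with planted genes shifted
additively inside a region.

## What the synthetic study does and does not show

* With 80 volumes and 264 nodes, per-subject estimates of σ_max (and hence
  all controllability values) carry a large shared noise component: node
  values are strongly correlated within subject.  Nodewise detections are
  therefore partly *all-or-nothing* across the cortex — a replicate
  occasionally lights up (or darkens) wholesale.  Type-I error control by
  FDR still holds on average (verified over ≥ 50 null replicates), but
  uniformity of null p-values is only testable across independent
  replicates, not by pooling dependent nodes; the validation suite samples
  one node per replicate for its Kolmogorov–Smirnov check.
* The recovered high-load modal-controllability deficit has both a
  node-specific and a group-global component (the redistribution slightly
  reshapes the dominant correlation mode).  Full-scale runs consequently
  show broad high-load differences, strongest at the affected
  frontoparietal nodes, and typically nothing at low load — qualitatively
  matching a graded, SZ-worst, high-load-specific pattern.
* Single-node average-controllability deficits are below the estimation
  noise floor at 80 volumes: they are present in the generating templates
  (and verified there) but are not reliably recovered by the nodewise test
  at study size.  Passing tests therefore demonstrate recovery of the
  modal deficit, calibration of the inference, and correctness of the
  machinery — not that every injected effect of any size is detectable in
  data this short.
* Real fMRI adds preprocessing artifacts, motion coupling, hemodynamics
  and site effects that the generator does not emulate.

## Numerical choices

* Correlations are clipped at |r| = 0.999999 before `atanh`; the diagonal
  is zeroed after the transform (self-coupling is not part of the
  adjacency).  Negative correlations are retained; no thresholding or
  sparsification is applied.
* Matrices asymmetric beyond 1e-10 are rejected, not silently symmetrized;
  within tolerance, `(A + Aᵀ)/2` is used before eigendecomposition.
* The nodewise ANCOVA is computed by vectorized least squares across all
  nodes at once (identical to per-node OLS, pinned against statsmodels in
  the tests); constant covariate columns are dropped, which also makes the
  covariate-free case reduce exactly to one-way ANOVA.
* Permutation p-values use the add-one convention and are never zero;
  permutation counts below 100 are rejected.
* The autocorrelation-preserving null fits its kernel scale by a small
  grid search minimizing the squared distance between the surrogate and
  observed lag-binned correlograms (6 quantile bins, 4 probe surrogates
  per candidate scale).
* Every generator and the pipeline are pure functions of (config, seed):
  one global seed spawns named per-stage substreams, and each stage output
  carries the configuration hash.

## Problem sizes in the validation suite

Calibration uses 50 effect-free replicates at 60 nodes and 120 subjects;
recovery uses 20 replicates at the full study scale (264 nodes, 303
subjects, high load).  Permutation checks use 1,000 permutations for the
planted-recovery simulations and 5,000 where a single p-value floor is
asserted; these sizes give stable Monte-Carlo estimates while keeping the
whole suite to a few minutes on one CPU.

## Known limitations

* The exact normalization and horizon conventions of the original
  controllability computation are not published in full; the canonical
  `M/(1 + σ_max)` discrete-time infinite-horizon convention is adopted and
  pinned by tests.  A different stabilization would shift per-node values
  monotonically; group contrasts are expected, but not guaranteed, to be
  rank-stable.
* Gray-matter partial-volume adjustment of the original voxel-space
  association toolchain is replaced by node-space analysis; pathway
  enrichment against external databases is out of scope (the surviving
  gene list is the terminal transcriptomic output).
* Whether within- and between-block dependence in real task fMRI matches
  the generator's independent-block assumption is unknown; the choice is a
  modeling convenience consistent with block-wise task design.
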
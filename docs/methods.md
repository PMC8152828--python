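# Methods

`painnet` re-implements, as a tested pipeline, a graph-theoretic analysis of
task-evoked brain networks: stimulation-weighted functional connectivity over a
fixed set of pain-responsive regions, weighted-signed modular decomposition, a
three-category hub taxonomy, and permutation-based condition contrasts. The
original scan data are not public, so the pipeline ships with a synthetic BOLD
generator that plants the reported modular structure; every stage is validated
end-to-end against that ground truth.

## Node universe

The network has 34 nodes — 17 named regions per hemisphere (operculo-insular,
somatosensory, cingulate, parietal, prefrontal, amygdala, hippocampus),
transcribed with their HCP-atlas area codes and MNI centroids into
`src/painnet/data/roi_table.tsv`. The primary auditory cortex (A1/Heschl) is
included only when an auditory control condition is analysed (36 nodes, 18 per
hemisphere). Node order is fixed — left-hemisphere block then right, in table
row order, A1 last within its block — and every matrix in the pipeline indexes
nodes that way. MNI coordinates are carried for reporting only; no computation
uses them.

The reference four-module partition
(`src/painnet/data/ground_truth_partition.json`) assigns the sensorimotor
module (SM: S1, S2, posterior/anterior insula, frontal operculum, SMA, MCC; 14
nodes), the medial fronto-parietal module (med-FP: precuneus, posterior and
anterior cingulate, orbitofrontal; 12 nodes), the lateral fronto-parietal
module (lat-FP: PPC, DLPFC; 4 nodes) and the limbic module (amygdala,
hippocampus; 4 nodes). For 36-node synthetic runs the two A1 nodes form their
own auditory module — a generator choice: the reference solution covers only
the 34 pain nodes, and an auditory latent lets audio-locked A1 coupling be
planted independently of the sensorimotor system.

## Synthetic cohorts

Two presets mirror the study's acquisition designs:

| preset | TR (s) | volumes/session | sessions | subjects | pain stimuli | audio stimuli |
|---|---|---|---|---|---|---|
| `group1` | 2.2 | 220 | 5 | 36 | 12 × 15 s | 8 × U(10, 50) s |
| `group2` | 2.56 | 205 | 3 | 24 | 12 × 25 s | — |

Single-condition sessions draw inter-stimulus intervals uniformly in
[12, 20] s (the bracket reported for the design), the lead-in from the same
range; infeasible packings raise an error reporting the maximal feasible
count. Group-1 sessions interleave the 12 pain and 8 audio events on one
non-overlapping timeline in shuffled order with short inter-event gaps
(U(1, 4) s): the real sessions pack roughly 400 s of stimulation into 484 s
with the two streams separated in time, and the emergent pain-to-pain interval
(≈ 24 s mean) lands on the reported 23 ± 13 s. Only the summary statistics of
the real inter-stimulus distributions are published, so the generator uses
these bracket ranges, not a fitted distribution.

Each node's signal is

    x_i(t) = √b · g(t) + √(w−b) · l_m(t) · α_m(t) + ν √(1−w) · e_i(t)
             + Σ_c γ_evoked[c, i] · r_c(t) + λ_i · confounds(t)

with unit-variance latents: a global factor `g`, one factor `l_m` per module,
and node-unique noise `e_i`, all AR(1) with lag-1 autocorrelation 0.3 to mimic
BOLD temporal smoothness (white-noise alternative behind a flag). With the
noise multiplier ν = 1, two same-module nodes correlate at `within_r` = w and
two nodes of different modules at `between_r` = b, exactly in expectation
(defaults w = 0.6, b = 0.1); ν = 0 makes same-module nodes identical copies,
which the removability and recovery tests exploit.

`r_c(t)` is the canonical-HRF-convolved boxcar of condition c. It enters
twice:

* **Evoked responses** — per-module amplitudes (pain: SM 1.0, med-FP/lat-FP
  0.6, limbic 0.2; audio: 0.5 with SM 0.3), jittered per subject
  (N(1, 0.15²), truncated at 0), with per-node overrides for A1 (pain 0.2,
  audio 1.5).
* **Stimulus-locked coupling** — the module-latent amplitude is multiplied by
  α_m(t) = 1 + Σ_c γ_coupling[c, m] · r_c(t)/max r_c (pain 2.0 on all pain
  modules, 0.2 on auditory; audio 1.0, auditory 2.5). This plants the
  phenomenon stimulation-weighting exists to detect: connectivity that
  strengthens during stimulation. Without it, a shared evoked time course
  *inflates full-session correlations more than weighted ones*, and weighting
  would have nothing to find.

Confounds are 8 nuisance series per session — six motion-like regressors
(random walks low-pass filtered below 0.005 Hz) and WM-/CSF-like AR(1) series
— standardized and mixed into each node with N(0, 0.1²) loadings. A master
seed fully determines the cohort (per-subject streams are spawned from a
`SeedSequence`, so cohorts are bit-reproducible).

What the generator does **not** emulate: spatial structure (no volumes, no
smoothing, no atlas extraction), physiological noise beyond AR(1)+drift,
heterogeneous node degree within modules, inter-subject anatomical
variability, and non-stationarities other than the planted stimulus-locked
coupling. Passing recovery tests therefore shows the pipeline's correctness
and sensitivity under its own assumptions, not performance on real scans.

## Preprocessing

Each node series is replaced by its least-squares residual against a joint
design of intercept + confound columns + discrete-cosine drift regressors up
to the cutoff (default 0.01 Hz; K = ⌊2·T·cutoff⌋ cosines, the SPM convention),
then z-scored per session. Regression and filtering are done in a single
projection — the two steps commute that way and the result is exactly
reproducible; a Butterworth alternative was rejected to avoid edge
transients. Residuals are exactly orthogonal to every regressor; collinear
confound columns and zero-variance residuals raise errors naming the
offenders. Note on the filter: a truncated DCT basis absorbs >99.9 % of a
linear drift's variance and ≥95 % of the *power* of an off-grid 0.005 Hz
sinusoid (≈10 % residual amplitude), while a 0.05 Hz signal passes with ≥95 %
amplitude; the stopband is enforced in power terms in the tests.

## Stimulation-weighted connectivity

The canonical HRF is the double-gamma kernel h(t) = g(t; 6, 1) − g(t; 16, 1)/6
(gamma densities, peak near 5 s), sampled every TR over 32 s and
peak-normalized. Per condition, the stimulus boxcar (1 during each event at
volume resolution) is convolved with h and the negative undershoot is clamped
to zero; the clamped regressor is the per-volume weight vector w_t. "Positive
and null parts" is read as this clamping: weights must be nonnegative for
weighted moments to be defined, and the clamp leaves rest volumes at exactly
zero influence.

The weighted Pearson correlation of nodes x, y is

    r_w(x, y) = cov_w(x, y) / √(var_w(x) · var_w(y)),
    cov_w(x, y) = Σ_t w_t (x_t − m_x)(y_t − m_y) / Σ_t w_t

which is invariant to positive rescaling of w (weights are deliberately not
renormalized) and reduces to ordinary Pearson for uniform weights. Session
matrices are Fisher-z transformed (atanh, |r| clipped at 1−1e-7 with a
warning) and averaged arithmetically across sessions into one matrix per
subject per condition — the combiner is not stated in the source analysis, so
mean-of-z is the default and weight-concatenation across sessions is available
behind `combine="concat"`.

## Thresholding, topology, nulls

Proportional thresholding ranks the n(n−1)/2 off-diagonal values by |z|
(descending) and keeps exactly ⌊d · n(n−1)/2⌋ of them with their signs, ties
broken lexicographically by (i, j); ranking by signed value is available
behind a flag. Subject matrices are thresholded, averaged into the group
matrix, and the group matrix re-thresholded at the same density. The grid is
0.10–0.50 in steps of 0.05 with 0.30 the reporting density.

Global metrics are computed on the binary view (the printed magnitudes of the
reference analysis are only attainable binarily): C is the mean binary
clustering coefficient (nodes of degree < 2 contribute 0), L the mean
shortest-path hop count over pairs of the giant component (with the covered
node fraction reported), and A the correlation across nodes between degree and
mean neighbor degree — the literal definition used by the source; Newman's
edge-end assortativity is also exposed. Small-worldness is
σ = (C/C_random)/(L/L_random) with the random means taken over a
shuffled-weight null ensemble: each realization permutes the upper-triangle
weights uniformly (preserving node count, edge count and the weight multiset
— positive and negative strength totals exactly) and re-runs the same
pipeline. The source describes both "random networks with same size and
number of links" and a value-shuffling procedure; the weight shuffle is
implemented as the single null construction. Ensemble sizes: 100 for
C_random/L_random, 5000 reserved for significance tests (both configurable).

## Signed modularity and its optimizer

Modularity of a labeling on a signed weighted graph follows the separate
positive/negative null-strength convention:

    Q = 1/(2w⁺ + 2w⁻) Σ_ij [ A_ij − ( s_i⁺ s_j⁺ / 2w⁺ − s_i⁻ s_j⁻ / 2w⁻ ) ] δ(c_i, c_j)

with s_i± the positive/negative strengths and 2w± their totals; the negative
terms vanish on all-positive graphs, recovering Newman–Girvan weighted Q. This
formulation is the single most consequential underdetermined choice and is
isolated in one function (`signed_modularity_value`), cross-checked in the
tests against hand-evaluated cases and an exhaustive enumeration oracle.

Optimization runs 100 independent restarts (the "100 iterations" of the
source's tabu/fast/repository/fast sequencing, read as restarts of the full
sequence), each: greedy agglomeration from singletons, local-reassignment
("fast") sweeps to convergence, a tabu phase (tenure 10, worsening moves
allowed, aspiration on a new global best, stop after 30 move iterations
without improvement), and a closing fast pass. The best labeling across
restarts is kept (first found among ties); module ids are canonicalized by
decreasing size, ties by smallest member index. All constants are fixed and
the search is deterministic given its seed. On every ≤9-node test graph the
optimizer attains the exhaustive-enumeration optimum.

## Node roles and hubs

Per node: binary degree k; unnormalized Brandes betweenness b on the binary
view (consistent with binary L; tied shortest paths share credit equally);
within-module degree z-score z_wmd = (κ_i − μ_module)/σ_module (population SD,
0 when σ = 0); participation coefficient PC = 1 − Σ_s (κ_is/k_i)², defined as
0 for isolated nodes (flagged). Hub taxonomy:

* **static** — degree above the per-node shuffled-weight null at permutation
  p < 0.01;
* **dynamical** — likewise for betweenness;
* **connector** — z_wmd > 1.0 and PC > 0.45. The source ties 0.45 to
  "mean PC + 1 SD" in the same sentence; the fixed threshold is the default
  and the recomputed mean+1SD variant is available via `pc_mode`.

On default synthetic cohorts the planted modules are internally homogeneous,
so group-level graphs rarely contain degree or betweenness outliers and the
static/dynamical flags are typically empty — the hub machinery is validated by
unit oracles and a null-calibration test (false-flag rate ≤ α + 2 SE on graphs
drawn from the null itself) rather than by the cohort runs.

## Permutation statistics

P-values use the add-one estimator p = (1 + #{null ≥ observed})/(1 + n_perm)
(two-sided: absolute deviation from the null mean), so the attainable floor is
1/(n_perm+1). Condition contrasts are paired sign-flip permutations: group-1
subjects experience both conditions, so under the null each subject's
pain−audio difference is sign-symmetric and signs are flipped independently
per subject (5000 flips by default; analysis drivers use 1000, which changes
only the p-value floor, 1/1001 instead of 1/5001, and Monte-Carlo noise of
order 1 %). Edge deltas are mean paired Fisher-z differences; the same
machinery applies to per-subject global metrics and intra/inter link
proportions. Two-sided tests are the default for edges (both directions are
of interest). Benjamini–Hochberg FDR is applied within each family — edges,
global metrics, link statistics — separately.

## Problem sizes

The test suite and the acceptance script run the full chain at reduced but
representative sizes chosen for a single CPU: recovery experiments use 12
subjects (group-1 design, 5 × 220 volumes) or 4-subject/2-session group-2
cohorts for repeated-seed sweeps; null ensembles use 100 realizations for
σ and ≤ 200 for hub calibration; contrasts use 1000 permutations. The planted
structure at default contrast (w − b = 0.5) is recovered with NMI = 1 at these
sizes, and recovery degrades monotonically as the contrast shrinks — the
regime where larger cohorts would matter.

## Known limitations

* The group graph at 30 % density on default cohorts is near-block-diagonal
  (the limbic module disconnects, as in the reference analysis where it had no
  intermodular links at that density), so L is computed on a giant component
  covering ~40 % of nodes there and σ is correspondingly large; at d ≥ 0.4
  the graph connects fully. Coverage is always reported alongside L.
* Degree-based hub flags are uninformative on homogeneous planted modules
  (see above).
* The weight-shuffle null destroys all topology; it does not preserve the
  degree sequence (a Maslov–Sneppen rewiring null is out of scope).
* Condition contrasts assume within-subject pairing; no pooled/unpaired
  variant is provided.
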
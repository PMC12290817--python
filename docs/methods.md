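# Methods

This note documents the models, numerical choices and limitations of
`commrsa`.  Everything quantitative stated here is computed by the test
suite or the examples; nothing is asserted that the code does not check.

## Design and sequence model

Fifteen recurring objects are nodes of a transition graph; a run presents
180 recurring trials (a constrained walk) plus 20 singular objects at
random positions, one trial per 3 s (2.5 s presentation + 0.5 s
transition), 200 trials per 600-s run, 18 runs per observer in the full
design.

*Modular graph*: three communities of five; within a community all pairs
adjacent except the two boundary ("linking") objects; the three
between-community edges form a ring over communities.  Every node has
degree 4, so single-step transition probabilities are uniform everywhere —
by construction only higher-order statistics separate conditions.  The
*complete* graph (degree 14) is the unstructured control; it carries the
same 5/5/5 partition as a counterfactual labeling so control analyses can
run unchanged.

Walks start at a uniform node; each step is uniform over the current
node's neighbors minus the previous node, which simultaneously forbids
immediate repetitions (X→X) and direct returns (X→Y→X).  The second step
excludes only the start.  Counterbalancing is a post-selection: among
`n_candidates` (default 200) candidate walks, keep the one minimizing the
sum of squared deviations of per-object counts from n/15 plus squared
deviations of directed-edge usage counts from their mean.  With 200
candidates the per-walk object-count SD drops to ≤ 2 (the 12 ± 1.9
appearances-per-run regime).

Sequence statistics are computed on the recurring-object walk with
singular trials excluded.  Pooled over 100 walks of 180 steps the median
repetition latency is 6 (structured; the design's reference value is 5.5 —
integer-valued gaps put the pooled median on a grid) and 10–11
(unstructured); mean community-episode length is ~9.5 trials ≈ 28.5 s
structured and 13/9 ≈ 1.44 under counterfactual labels (Markov closed
form 1/(1 − 4/13), verified by simulation).  Mean return time on the
modular walk is 15 steps (regular graph).

## Surrogate response model

Per parcel, trial k yields a vector in R^(Nt·Nvox):

    x_k = mu_obj(k) + beta (c_comm(k) − mu_bar) + drift_k + eps_k

| parameter | meaning | default | rationale |
|---|---|---|---|
| `n_vox`, `n_t` | voxels, time points per trial | 200, 9 | typical parcel (45–462 voxels), 9 analysis frames at 1-s resolution |
| `identity_snr` | class-mean dispersion / noise SD, per coordinate | 0.09 | gives leave-one-run-out decoding accuracy ≈ 0.5 at the full design — clearly above the 1/15 chance level without being trivial |
| `community_beta` | signed community effect | 0 | + pushes community centroids apart (between distances grow), − pulls them together |
| `drift_rho`, `drift_sd` | AR(1) coefficient and stationary SD of a shared additive drift, reset per run | 0.65, 0.62 | calibrated so the delay-conditional mean distance dips ≈ 5% at latencies < 4 trials (measured −5.1% at the defaults) |
| `noise_sd` | isotropic trial noise | 1.0 | scale reference |

Class means are isotropic Gaussian draws; community centroids derive from
them, so the community term scales with the identity signal.  A
consequence worth knowing: the between-community distance modulation is
(2β + β²)/5 of the identity variance share — asymmetric in β and bounded
below by −1/5 (at β = −1).  Negative sensitivity is therefore intrinsically
harder to detect than positive sensitivity of equal |β|, and the
parameter-recovery checks use the full 8-observer design for it.

What the generator does *not* emulate: hemodynamic convolution and window
overlap (drift is a direct stand-in for their autocorrelation), voxel-level
spatial structure, motion artifacts, and the ~2% distance *excess* at
delays 6–15 seen in real data (AR(1) gives a monotone profile; no
mechanism for the excess is modeled).  Passing tests therefore show the
statistics behave correctly under temporally autocorrelated, community-
structured Gaussian responses — not that real tissue behaves this way.

## Discriminant subspace (direct LDA)

With Ndim up to ~4000 and a few thousand trials, within-class scatter is
rank-deficient, so the classical LDA eigenproblem is ill-posed.  Direct
LDA: (1) eigendecompose the between-class scatter via SVD of the weighted
centered class-mean matrix (never materializing Ndim×Ndim), keep
eigenvectors with eigenvalue > 1e−10 × leading (at most κ−1 = 14), whiten;
(2) eigendecompose the within-class scatter inside that space, whiten with
ridge 1e−6 × mean eigenvalue; (3) standardize every retained dimension to
unit variance on the training data.  Eigenvector signs follow the
largest-magnitude-component-positive convention, so results are
deterministic.  The final standardization is what makes normalized
amplitudes ⟨a⟩ ≈ 0.99 and unrelated-pair distances ⟨d⟩ ≈ 1.40 (the
14-sphere baseline 1.4017) hold by construction on fitted data.

DLDA restricts attention to the between-class column space before seeing
within-class structure, so on small well-posed problems it can concede a
few percent of the optimal Fisher criterion relative to the generalized
eigenproblem (tested); it is invariant to global affine rescaling but not
to arbitrary invertible linear maps.

**Leave-one-run-out projection for distance analyses.**  Fitting the
subspace on all runs and measuring distances on the same trials couples
the whitening with the evaluated trials' drift: episode-shared drift leaks
into estimated class means, and whitening then distorts within- vs
between-community geometry.  Empirically this left drift-only null parcels
at t_BW ≈ +4…6 *after* residual correction.  All distance analyses
therefore project each run with a subspace fit on the remaining runs
(`analysis.project_loro`); with it, null parcels are flagged in ~4% of
replicates at α = 0.05.  The in-sample fit remains available and is used
where the statistic is defined on fitted data (the ⟨a⟩/⟨d⟩ regime, the
PCA-comparison report, the persisted per-parcel subspace).

## Distances, delay profile, correction

Pairwise distances are RMS-normalized Euclidean distances between
projected responses, computed for all within-run pairs of recurring
trials; latency is the trial-index difference (singular trials occupy
index slots, so latency counts elapsed trials; seconds = 3 × trials).
The per-parcel delay profile T_w(Δ) pools observers and runs (per-observer
profiles behind a flag) and includes same-object pairs (a switch excludes
them; measured impact on null calibration: none).  Correction:
d_corr(Δ) = d(Δ) − T_w(Δ) + ⟨T_w⟩; a latency absent from the profile
raises rather than silently extrapolating.  The correction is idempotent
and pins every delay-conditional mean to ⟨T_w⟩ by construction.

## Community statistics

Community statistics use corrected distances of *distinct*-object pairs
only (same-object pairs would conflate identity with community).  t-tests
are pooled-variance Student by default (Welch by flag).  The latency sweep
runs τ_LB = 1…30 with Benjamini–Hochberg correction across parcels within
each bound; τ_sig is the largest bound up to which the parcel is
significant at every smaller bound, and only τ_sig = 30 flags a parcel.
Bounds with an empty group are undefined and non-significant, so a parcel
whose long-latency data run out cannot be declared sensitive.  Pair-type
scores t_SA, t_DA, t_SN, t_DN test each type against the pooled distances
of all four types; the pool includes the tested type's own members
(overlapping-sample two-sample t-test, the documented reading of the
reference definition).  In recovery runs t_SA moves opposite to t_BW and
t_DN with it, reproducing the expected sign structure.

A caveat the tests quantify rather than hide: distances sharing a trial
are dependent, so pair-level t-statistics are mildly overdispersed under
drift (SD ≈ 1.2–1.4 instead of 1).  The τ_sig = 30 consistency requirement
absorbs most of this in practice (drift-only nulls flagged in ≤ 5% of
replicates); the drift-free type-I rate at τ_LB = 1 measured 7% at nominal
5%.

## Identity decoding and group inference

Leave-one-run-out cross-validation; the subspace and centroids are fit
within each fold (no leakage; `fitted_on` records the training runs);
nearest-centroid ties break toward the lowest object id.  Folds whose
training data miss a class are skipped with a warning.  The group test is
the global-null minimum statistic: B ≥ 100 within-run label permutations
(same scheme for every observer per iteration), p = (1 + #{null ≥
observed})/(B + 1).  This is a deliberate reduction of full prevalence
inference to its global-null core.

## Geometry

Per (parcel, observer): 15×15 matrices of mean corrected distances per
object pair within each run, averaged over runs (pairs never co-occurring
in a run are excluded from that run's average, not imputed).  Averaging
across observers is made meaningful by first averaging each matrix over
the graph's automorphism group — all 1296 = 6 ring symmetries × 6³
internal-node permutations that preserve adjacency and community
membership, each verified against the adjacency matrix at construction.
The exact group average is the default (it is a projection: idempotent,
grand-mean preserving); a random-sampling mode exists for fidelity checks
and converges to it.  Embedding uses nonmetric (stress-1) MDS, 20 restarts
with a fixed seed; metric MDS behind a flag.  The three-fold symmetry of
embedded maps (community centroids equidistant from the center) is a
consequence of the averaging, not evidence about the data.  The
internal/linking summary reports the six cells {internal–internal,
internal–linking, linking–linking} × {within, between}; the three
linking–linking within-community pairs are exactly the SN pairs.

## Pipeline

`run_pipeline` executes simulate → subspace → distances → community →
identity → geometry from a single validated config (YAML/JSON), writing
TSV/HDF5 outputs and a manifest with per-stage timings and SHA-256
checksums; identical config + seeds reproduce identical text outputs.
All randomness flows through explicitly seeded generators.

## Problem sizes used by the quantitative checks

Chosen as the package's desk-scale working points: walk statistics use 100
sequences × 180 steps; the spurious-sensitivity control and null
calibration use 100 replicates of a single-observer, 18-run study with
45-dimensional parcels (drift on and off respectively); signed parameter
recovery uses the full 8-observer, 18-run design at 45 dimensions with
β = +0.6 and β = −1.0 — the documented detection thresholds at that scale;
the normalization and geometry checks use 6-run studies at 200 and 45
dimensions.

## Known limitations

* The AR(1) drift reproduces the short-latency distance dip but not the
  small mid-latency excess of real data.
* Negative community effects saturate (see above); detecting weak negative
  β requires the full multi-observer design.
* Pair-level t-tests ignore trial-sharing dependence (as in the reference
  analysis); interpret per-bound p-values through the consistency sweep,
  not in isolation.
* The minimum-statistic test addresses the global null only, not
  prevalence.
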
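# Methods

## The model

The package implements an epidemic spreading model (ESM) of amyloid-beta
propagation over an anatomical connectome.  Each region `i` of a weighted,
symmetric region-by-region connectivity matrix carries a deposition
probability `P_i(t) ∈ [0, 1]`.  Pathology grows by exogenous reception of
misfolded protein from connected regions and endogenous production at the
epicentres, and shrinks by clearance:

    dP_i/dt = (1 − P_i) · ε_i(t) − δ · P_i
    ε_i(t)  = 1 − (1 − β·P0·1[i ∈ epicentres]) · ∏_j (1 − β·Ĉ_ij·P_j(t))

with global production rate `β` (per year), global clearance rate `δ`
(per year), onset age `t0` (epicentres seeded at level `P0`, default 0.01),
and `Ĉ` the connectome on a common transmission scale.  The per-connection
terms `β·Ĉ_ij·P_j` are treated as independent transmission probabilities and
combined with the complement-product rule, making the system an SIS-type
epidemic: with `δ = 0` every region reachable from the seed saturates at 1;
with `β = 0` the seed decays exponentially.  The right-hand side lives in a
single function (`esm_core.esm_rhs`) so that alternative functional forms
can be swapped without touching the integrator or the fitting machinery.

### Connectome scaling

`Ĉ` defaults to the raw weights divided by the maximum row sum — one global
constant that bounds every transmission probability while preserving
relative connection strengths (`normalization="global"`).  Per-row
normalization is available (`"row"`) but is *not* the default for a
structural reason: the leading right eigenvector of a row-stochastic matrix
is constant, so row-normalized spreading converges to a spatially flat
pattern and epicentre information survives only transiently.  With global
scaling, strongly connected regions genuinely receive more transmission and
regional heterogeneity persists into the late dynamics, which is what makes
epicentre inference possible at realistic noise levels.

### Integration

Fixed-step RK4 with `dt = 0.1` year (0.25 year on the reduced grid), state
clamped to [0, 1] after every stage and step.  Halving `dt` changes the
final state by less than 1e-4 at default parameters.  Because the system is
autonomous, a subject's prediction depends on onset only through the elapsed
duration `age − t0`; one trajectory per `(β, δ, epicentre)` therefore serves
every subject and candidate onset.  This trajectory sharing is what makes
whole-cohort sweeps over all 39 bilateral candidate epicentres affordable
(one grid of integrations per candidate, independent of cohort size).

## Fitting

Per-subject parameters are found by exhaustive grid search maximizing the
Pearson r² between the simulated and observed regional pattern at the
subject's age.  The default grid is 20 log-spaced values of `β` and `δ` in
[1e-3, 1] per year, onsets every 2 years, `P0` fixed; the "reduced" grid
(8 × 6 rates, onsets every 4 years) is used for cohort-scale work.  Exact
ties resolve deterministically to the least-aggressive explanation: smaller
`β`, then later onset, then smaller `δ`.  A constant observed pattern has no
defined correlation and yields a flagged degenerate fit with r² = 0.

Two cohort-level metrics summarize a fit: the mean within-subject r², and
the global fit — the r² between the cohort-averaged observed and predicted
patterns.

### Identifiability and onset anchoring

The model family is invariant, to first order in the transmission terms,
under the joint rescaling `(β, δ, t) → (c·β, c·δ, t/c)`: a scale-free r²
objective identifies `β·duration` and `δ/β` well but splits them poorly.
Clearance is partially identified through its effect on the equilibrium
shape; absolute rates are not.  When an external disease clock exists — in
autosomal-dominant cohorts the family's expected symptom-onset age dates the
start of amyloid accumulation roughly two decades earlier — the fit can
restrict candidate durations to `anchor ± window` years
(`duration_anchor` / `duration_window` in `fit_esm_cohort`), which pins the
time scale and makes `β` and `δ` recoverable.  Anchoring is off by default;
the parameter-recovery analyses enable it and evaluate rate recovery on the
log scale, the natural scale for rates drawn log-spaced across decades.

## Regional probabilities and positivity

PET voxels are scored against a bootstrapped extreme-value distribution
(EVD) of the reference region: reference voxels trimmed to their 5–95%
percentile band, 40 000 subsamples with replacement (subsample size defaults
to the number of retained voxels), one extreme statistic per subsample — the
maximum for a cerebellar-cortex reference, the 75th percentile for the
hotter brainstem reference.  A voxel's deposition probability is the
fraction of EVD entries strictly below it; ties count as not exceeded.
Regional probabilities are voxel means; empty regions are reported missing,
never zero.  For cohorts with a reliable amyloid-negative control group,
carrier probabilities can be re-expressed as |z| against the pooled control
distribution per region, min–max scaled back to [0, 1] across all carrier
observations; a region with zero control variance raises rather than being
silently patched.

Amyloid positivity uses a composite mean over bilateral precuneus, superior
frontal, rostral middle frontal, lateral/medial orbitofrontal and
superior/middle temporal regions, for both a SUVR-scale value and the
deposition-probability value.  A two-component Gaussian mixture is fitted
over the whole cohort (best of 20 random-from-data EM restarts at a fixed
seed; k-means initialization systematically misses a narrow negative spike
next to a broad positive mode); the cutoff is the equal-density
(posterior-0.5) crossing between the component means, found by root
bisection.  Fits with a vanishing component weight (< 0.02), collapsed
variance, or component separation below 2 SD of the tighter component are
rejected as degenerate with advice to use a fixed threshold.  A subject is
positive only if strictly above *both* cutoffs; thresholds transfer across
cohorts as plain parameters.

## Epicentre inference

Candidates are the 39 bilateral region pairs of the 78-region atlas, paired
by hemisphere tag; left and right homologues are seeded jointly.  Parameters
are refit per candidate (conservative), and the winner is the candidate with
the best within-subject r², ties broken alphabetically.  Each assignment
records the r² margin to the runner-up; an optional flag marks margins
< 0.01 as ambiguous.  Subgroups follow the winning region: DMN (posterior
cingulate, caudal/rostral anterior cingulate, precuneus, medial
orbitofrontal), Striatum (caudate, putamen), else Other.

Connectivity specificity is tested against rewired connectomes:
Maslov–Sneppen double-edge swaps (10 accepted swaps per edge) scramble the
binary topology while preserving every node's degree; the original edge
weights are then re-assigned in rank order of the product of the endpoints'
original strengths, preserving the weight multiset exactly and node
strengths to Spearman ρ ≥ 0.9.  The one-sided exceedance p-value is
`(1 + #{null ≥ observed}) / (1 + n_null)` with percentile 95% intervals.

## Synthetic data

Real cohorts of this kind are access-restricted, so all fixtures are
generated with recorded ground truth.

**Connectome** — 78 regions with DKT-style labels at approximate anatomical
centroid coordinates, mirrored across hemispheres.  Weights follow
`exp(−d/25 mm)` distance decay with symmetric lognormal variability;
within-module connections (cingulum/default-mode core, basal-ganglia loop,
frontoparietal, visual, sensorimotor-temporal systems) are boosted 3×,
reflecting long-range bundles; the graph is thresholded to 20% density and
scaled into (0, 1].  Homotopic edges are kept.  The community structure is
load-bearing: without it, seed location barely shapes moderately advanced
patterns and epicentre inference degenerates.

**Cohorts** — subjects draw a class from the (DMN, Striatum, Other) mixing
proportions (default 0.60/0.13/0.27, echoing the relative frequencies
reported for mutation-carrier cohorts, as a realistic default only).  DMN
and Striatum subjects draw a bilateral epicentre from the corresponding
pool, grid-point parameters (production 0.1–0.7/yr, clearance ≤ 0.06/yr,
durations 14–38 y), and are forward-simulated; draws are retried (up to 12
attempts, keeping the closest) until the mean burden falls in 0.10–0.55,
emulating amyloid-positive scans of a predominantly presymptomatic-to-early
cohort — clearly established deposition short of the late-stage plateau
where patterns flatten and carry no epicentre information.  "Other" subjects
are the low-amyloid false-positive class: near-zero cortical signal with
elevated pallidum/thalamus uptake (nonspecific binding).  Striatum-class
subjects are drawn 8 years younger by default to exercise the demographic
contrasts.  EYO is tied to the disease clock as `duration − 20 y` plus
familial noise (SD 3 y).  Observation noise is additive truncated Gaussian
(default SD 0.02), clipped to [0, 1].  A synthetic composite SUVR tracks
true burden for the dual positivity rule.

**What the generator does not emulate** — scanner physics (PSF, partial
volume), off-target binding beyond the pallidum/thalamus class, atrophy,
longitudinal parameter drift, or tractography biases.  Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline under its own generative model, not clinical validity on real PET.

**Longitudinal pairs** — each subject is re-simulated forward under its true
parameters; scripted epicentre switches overlay the new epicentre's
same-stage signal while damping the old focal pattern to 30%, producing a
known transition truth.

## Analysis sizes and runtimes

Cohort-scale analyses (sweeps, null ensembles, the pipeline) use the reduced
grid; experiments use 50–100 subjects, 100 null connectomes, and run in a
few minutes each on one CPU.  These sizes are the package's defaults for
synthetic studies; all are configurable.

## Known limitations

- The ODE form is a reconstruction from the verbal model definition
  (production + exogenous reception − clearance); region-specific clearance
  and other refinements of earlier ESM variants are deliberately collapsed
  into global `β`, `δ`.
- The r² objective is scale-free; predicted magnitudes are reported but not
  matched, and absolute rates are unidentifiable without onset anchoring
  (see above).
- Winner-take-all epicentre assignment ignores near-ties; the recorded
  margin (and the optional ambiguity flag) is the mitigation.
- The GMM positivity cutoff assumes a genuinely bimodal composite
  distribution; cohorts without a negative mode should use fixed thresholds.
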
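# esm-abeta

Epidemic spreading model (ESM) analysis of amyloid-beta deposition over
anatomical brain connectomes.

Amyloid-beta is thought to propagate trans-neuronally: misfolded protein
spreads from region to region along axonal connections, modulated by each
individual's production and clearance rates.  This package implements that
hypothesis as a fittable generative model, for researchers who want to ask,
per subject: *how well does connectivity explain this amyloid pattern, and
where did it most likely start?*  It covers the full analysis sequence —
converting PET signal to regional deposition probabilities, data-driven
amyloid-positivity thresholds, per-subject model fitting, epicentre sweeps
with DMN/Striatum/Other phenotyping, connectome null-model validation, and
the group statistics around them — and ships a synthetic-data generator with
full ground truth, since real cohorts of this kind are access-restricted.

## The model

Each region *i* of a weighted connectome carries a deposition probability
*P<sub>i</sub>(t)*:

    dP_i/dt = (1 − P_i) · ε_i(t) − δ · P_i

    ε_i(t) = 1 − (1 − β·P₀·1[i ∈ epicentres]) · ∏_j (1 − β·Ĉ_ij·P_j(t))

where β is the global production/transmission rate (yr⁻¹), δ the global
clearance rate (yr⁻¹), Ĉ the connectivity matrix on a common transmission
scale, and the epicentres start at seed level P₀ at onset age t₀.  The
per-subject (β, δ, t₀) are found by grid search maximizing the Pearson r²
between simulated and observed regional patterns.  Cohort fits report the
mean within-subject r² and the *global fit* (r² between cohort-averaged
observed and predicted patterns), each validated against 100
degree/strength-preserving rewired connectomes.

See `docs/methods.md` for the full model description, identifiability
analysis, and the synthetic-data design.

## Worked example

```python
import numpy as np
import esm_abeta as ea

C = ea.make_synthetic_connectome(seed=0)            # 78-region bilateral atlas
grid = ea.ParameterGrid.reduced()
patterns, covars, truth = ea.simulate_cohort(
    C, n_subjects=12, mixing=(0.7, 0.3, 0.0), noise_sd=0.02, seed=5
)

# a-priori epicentre experiment: caudal anterior + posterior cingulate
epi = ea.EpicentreSet([
    "L_caudal_anterior_cingulate", "R_caudal_anterior_cingulate",
    "L_posterior_cingulate", "R_posterior_cingulate",
])
report = ea.fit_esm_cohort(patterns.values, C, epi, covars["age"].to_numpy(), grid)
print(f"global fit r2 = {report.global_r2:.3f}")
print(f"mean within-subject r2 = {report.mean_within_subject_r2:.3f}")

nulls = ea.build_null_ensemble(C, n_null=20, base_seed=100)
st = ea.null_model_significance(report, patterns.values, epi,
                                covars["age"].to_numpy(), nulls, grid)
print(f"null global r2 = {st.global_mean:.3f} "
      f"[{st.global_ci[0]:.3f}, {st.global_ci[1]:.3f}], p = {st.p_global:.3f}")

# data-driven epicentre sweep over all 39 bilateral candidates
assignments = ea.sweep_epicentres_cohort(
    patterns.values, C, covars["age"].to_numpy(), grid=grid
)
hits = sum(a.subgroup == t for a, t in
           zip(assignments, truth.table["true_subgroup"]))
print(f"subgroup recovery: {hits}/12")
```

Output:

```
global fit r2 = 0.990
mean within-subject r2 = 0.926
null global r2 = 0.889 [0.864, 0.906], p = 0.048
subgroup recovery: 11/12
```

The cohort was generated by the model itself, so the true connectome fits
nearly perfectly (r² = 0.99) and — the crucial control — still beats all 20
rewired null connectomes (p = 1/21 ≈ 0.048): the fit is specific to the
true wiring, not an artefact of smooth regional signal.  The sweep recovers
the generating epicentre subgroup for 11 of 12 subjects at noise SD 0.02;
each assignment also records the r² margin to the runner-up candidate, which
is small when several epicentres explain a pattern almost equally well.

A command-line interface mirrors the library
(`esm-abeta synth|connectome|fit|sweep|run`), and
`esm-abeta run --config pipeline.yaml --out-dir run/` executes the full
sequence — positivity → a-priori fits → null significance → sweep →
subgroup statistics — writing one CSV report per stage plus the resolved
config; reruns with the same config are byte-identical.

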
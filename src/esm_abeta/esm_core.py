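"""Epidemic spreading model (ESM): forward simulation and per-subject fitting.

The model tracks, for every region ``i`` of a weighted anatomical connectome,
the probability ``P_i(t)`` that the region carries misfolded-protein
(amyloid-beta) deposits.  Each region gains pathology by exogenously receiving
misfolded protein from connected regions and (at the epicentres) by endogenous
production, and loses it through clearance:

    dP_i/dt = (1 - P_i) * eps_i(t) - delta * P_i

    eps_i(t) = 1 - (1 - beta * P0 * [i in epicentres])
                   * prod_j (1 - beta * Chat_ij * P_j(t))

where ``Chat`` is the connectome on a common transmission scale, ``beta``
the global production/transmission rate (per year), ``delta`` the global
clearance rate (per year), and ``P0`` the epicentre seed level.  The
infection-like probability ``eps_i`` combines independent per-connection
transmission events, so the system is an SIS-type epidemic on the connectome:
with no clearance every reachable region saturates at 1, with no production
the seed decays exponentially.

By default ``Chat`` is the weight matrix divided by its maximum row sum — a
single global constant that bounds every per-connection transmission
probability while preserving the relative connection strengths, so that
strongly connected regions genuinely receive more transmission and regional
heterogeneity persists in the dynamics.  Per-row normalization
(``normalization="row"``) is also available but makes the spreading
asymptotically flat: the leading right eigenvector of a row-stochastic
matrix is constant, so epicentre information survives only transiently.

The right-hand side is isolated in :func:`esm_rhs` so alternative functional
forms can be swapped without touching the integrator or the fitting code.

Fitting is an exhaustive grid search over (beta, delta, onset age) maximizing
the Pearson r^2 between the simulated and the observed regional pattern at
the subject's age.  Because the ODE is autonomous, a subject's prediction
depends on onset only through the elapsed duration ``age - t0``; one
trajectory per (beta, delta, epicentre) therefore serves every subject and
every candidate onset, which is what makes whole-cohort epicentre sweeps
tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectome import ConnectivityMatrix, NullEnsemble, normalize_rows

__all__ = [
    "ESMParameters",
    "EpicentreSet",
    "ESMFit",
    "ParameterGrid",
    "CohortFitReport",
    "NullFitStatistics",
    "esm_rhs",
    "simulate_esm",
    "fit_esm_subject",
    "fit_esm_cohort",
    "null_model_significance",
    "pearson_r2_matrix",
]


@dataclass
class ESMParameters:
    """Global spreading parameters for one subject.

    production_rate (beta) and clearance_rate (delta) are probability rates
    per year; onset_age (t0) is the age at which the epicentres are seeded at
    ``seed_level`` (P0).
    """

    production_rate: float
    clearance_rate: float
    onset_age: float
    seed_level: float = 0.01

    def __post_init__(self) -> None:
        if self.production_rate < 0 or self.clearance_rate < 0:
            raise ValueError("rates must be nonnegative")
        if not (0 < self.seed_level <= 0.1):
            raise ValueError("seed_level must lie in (0, 0.1]")


@dataclass
class EpicentreSet:
    """Regions seeded at onset; usually one or two bilateral pairs."""

    region_names: list[str]

    def __post_init__(self) -> None:
        if not self.region_names:
            raise ValueError("epicentre set must be nonempty")

    def indices(self, C: ConnectivityMatrix) -> np.ndarray:
        idx = []
        lower = [lab.lower() for lab in C.region_labels]
        for name in self.region_names:
            try:
                idx.append(lower.index(name.lower()))
            except ValueError:
                raise KeyError(f"epicentre region {name!r} not in connectome") from None
        return np.asarray(idx, dtype=int)


@dataclass
class ESMFit:
    """One subject's fitted model: parameters, prediction, goodness of fit."""

    params: ESMParameters
    epicentres: EpicentreSet
    predicted: np.ndarray
    within_subject_r2: float
    trajectory: np.ndarray | None = None
    trajectory_times: np.ndarray | None = None
    degenerate: bool = False


@dataclass
class ParameterGrid:
    """Search grid for (beta, delta, onset) plus integration settings.

    Onset is parameterized by elapsed duration ``age - t0``; ``durations``
    lists the candidate durations in years and is filtered per subject to
    ``duration < age`` so that t0 stays positive and below the scan age.
    """

    betas: np.ndarray = field(
        default_factory=lambda: np.logspace(-3, 0, 20)
    )
    deltas: np.ndarray = field(
        default_factory=lambda: np.logspace(-3, 0, 20)
    )
    durations: np.ndarray = field(
        default_factory=lambda: np.arange(1.0, 60.0, 2.0)
    )
    dt: float = 0.1
    seed_level: float = 0.01
    normalization: str = "global"  # "global" (max row sum) or "row"

    def __post_init__(self) -> None:
        self.betas = np.sort(np.asarray(self.betas, dtype=float))
        self.deltas = np.sort(np.asarray(self.deltas, dtype=float))
        self.durations = np.sort(np.asarray(self.durations, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.normalization not in ("global", "row"):
            raise ValueError("normalization must be 'global' or 'row'")

    @classmethod
    def reduced(cls) -> "ParameterGrid":
        """Coarse grid used for cohort-scale sweeps: 8 x 6 rate combinations,
        durations every 4 years, quarter-year integration steps."""
        return cls(
            betas=np.logspace(-2, 0, 8),
            deltas=np.logspace(-2.5, -0.5, 6),
            durations=np.arange(2.0, 42.0, 4.0),
            dt=0.25,
        )


@dataclass
class CohortFitReport:
    """Per-subject fits plus the two headline metrics: the mean within-subject
    r^2 and the global fit (r^2 between cohort-averaged observed and
    predicted patterns)."""

    fits: list[ESMFit]
    mean_within_subject_r2: float
    global_r2: float
    predicted: np.ndarray
    epicentres: EpicentreSet


@dataclass
class NullFitStatistics:
    """Fit metrics re-computed against an ensemble of rewired connectomes."""

    null_global: np.ndarray
    null_within: np.ndarray
    global_mean: float
    global_ci: tuple[float, float]
    within_mean: float
    within_ci: tuple[float, float]
    p_global: float
    p_within: float
    observed_global: float
    observed_within: float


def esm_rhs(
    P: np.ndarray,
    C_hat: np.ndarray,
    beta,
    delta,
    epi_mask: np.ndarray,
    seed_level: float,
) -> np.ndarray:
    """Time derivative of the regional deposition probabilities.

    Supports batched states: ``P`` of shape ``(..., n)`` with ``beta``/
    ``delta`` broadcastable over the leading axes.  ``epi_mask`` is the 0/1
    indicator of epicentre regions (endogenous production term).
    """
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    transmit = beta[..., None, None] * C_hat * P[..., None, :]
    survive = np.prod(1.0 - transmit, axis=-1)
    endo = 1.0 - beta[..., None] * seed_level * epi_mask
    eps = 1.0 - endo * survive
    return (1.0 - P) * eps - delta[..., None] * P


def _rk4_trajectory(
    C_hat: np.ndarray,
    betas: np.ndarray,
    deltas: np.ndarray,
    epi_idx: np.ndarray,
    snapshot_steps: np.ndarray,
    dt: float,
    seed_level: float,
) -> np.ndarray:
    """Integrate a batch of (beta, delta) systems from seeding, recording the
    state at the requested step indices.

    Returns an array of shape ``(batch, len(snapshot_steps), n)``.  The state
    is clamped to [0, 1] after every stage and step.  Computes exactly
    :func:`esm_rhs` but with ``beta * C_hat`` precomputed per batch member
    and reused scratch buffers (the integrator is the hot path of the grid
    search).
    """
    n = C_hat.shape[0]
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    deltas = np.atleast_1d(np.asarray(deltas, dtype=float))
    batch = betas.shape[0]
    epi_mask = np.zeros(n)
    epi_mask[epi_idx] = 1.0
    A = betas[:, None, None] * C_hat  # (batch, n, n)
    endo = 1.0 - betas[:, None] * seed_level * epi_mask  # (batch, n)
    T = np.empty_like(A)
    d_col = deltas[:, None]

    def rhs(P: np.ndarray) -> np.ndarray:
        np.multiply(A, P[:, None, :], out=T)
        np.subtract(1.0, T, out=T)
        eps = 1.0 - endo * T.prod(axis=-1)
        return (1.0 - P) * eps - d_col * P

    P = np.zeros((batch, n))
    P[:, epi_idx] = seed_level
    n_steps = int(np.max(snapshot_steps)) if snapshot_steps.size else 0
    out = np.empty((batch, snapshot_steps.size, n))
    want = {int(s): k for k, s in enumerate(snapshot_steps)}
    if 0 in want:
        out[:, want[0]] = P
    for step in range(1, n_steps + 1):
        k1 = rhs(P)
        k2 = rhs(np.clip(P + 0.5 * dt * k1, 0.0, 1.0))
        k3 = rhs(np.clip(P + 0.5 * dt * k2, 0.0, 1.0))
        k4 = rhs(np.clip(P + dt * k3, 0.0, 1.0))
        P = P + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(P)):
            raise FloatingPointError(
                "ESM integration produced non-finite state; use a smaller dt"
            )
        np.clip(P, 0.0, 1.0, out=P)
        if step in want:
            out[:, want[step]] = P
    return out


def _transmission_matrix(C: ConnectivityMatrix, mode: str = "global") -> np.ndarray:
    """Connectome on the transmission scale used inside the ODE.

    ``global`` divides all weights by the maximum row sum (one constant for
    the whole matrix, preserving relative strengths); ``row`` normalizes each
    row to sum to 1.  Matrices already flagged normalized pass through.
    """
    if C.normalized:
        return C.weights
    if mode == "row":
        return normalize_rows(C).weights
    if mode == "global":
        smax = C.weights.sum(axis=1).max()
        return C.weights / smax if smax > 0 else C.weights
    raise ValueError("normalization must be 'global' or 'row'")


def simulate_esm(
    C: ConnectivityMatrix,
    params: ESMParameters,
    epicentres: EpicentreSet,
    eval_age: float,
    dt: float = 0.1,
    record_trajectory: bool = True,
    normalization: str = "global",
) -> ESMFit:
    """Forward-simulate the ESM from onset to ``eval_age``.

    The connectome is put on the transmission scale internally (global
    max-row-sum scaling by default) unless already flagged as normalized.
    Emits a warning when ``beta * max(Chat) >= 1`` (the per-connection
    transmission probabilities leave [0, 1] and the product form loses its
    interpretation).
    """
    if eval_age <= params.onset_age:
        raise ValueError("eval_age must exceed the onset age")
    C_hat = _transmission_matrix(C, normalization)
    beta = params.production_rate
    if beta * C_hat.max() >= 1.0:
        import warnings

        warnings.warn(
            "beta * max(normalized connectivity) >= 1; transmission "
            "probabilities saturate and the product form is suspect"
        )
    duration = eval_age - params.onset_age
    n_steps = max(1, int(round(duration / dt)))
    steps = np.arange(n_steps + 1) if record_trajectory else np.array([n_steps])
    states = _rk4_trajectory(
        C_hat,
        np.array([beta]),
        np.array([params.clearance_rate]),
        epicentres.indices(C),
        steps,
        dt,
        params.seed_level,
    )[0]
    final = states[-1]
    traj = states if record_trajectory else None
    times = params.onset_age + steps * dt if record_trajectory else None
    return ESMFit(
        params=params,
        epicentres=epicentres,
        predicted=final,
        within_subject_r2=float("nan"),
        trajectory=traj,
        trajectory_times=times,
    )


def pearson_r2_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between every row of A and every row of B.

    Rows with zero variance yield 0 (undefined correlations are treated as
    no-fit rather than propagating NaN).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac**2).sum(axis=1))
    nb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ Bc.T) / np.outer(na, nb)
    r = np.where(np.isfinite(r), r, 0.0)
    return r**2


def _grid_snapshots(
    C: ConnectivityMatrix,
    epicentres: EpicentreSet,
    grid: ParameterGrid,
    durations: np.ndarray,
):
    """Simulate all (beta, delta) combinations once, snapshotting at the
    requested durations.  Returns (betas_flat, deltas_flat, states) with
    states of shape (n_combo, n_durations, n_regions)."""
    C_hat = _transmission_matrix(C, grid.normalization)
    bb, dd = np.meshgrid(grid.betas, grid.deltas, indexing="ij")
    betas_flat = bb.ravel()
    deltas_flat = dd.ravel()
    steps = np.round(durations / grid.dt).astype(int)
    states = _rk4_trajectory(
        C_hat,
        betas_flat,
        deltas_flat,
        epicentres.indices(C),
        steps,
        grid.dt,
        grid.seed_level,
    )
    return betas_flat, deltas_flat, states


def _select_best(
    r2_flat: np.ndarray,
    beta_flat: np.ndarray,
    delta_flat: np.ndarray,
    dur_flat: np.ndarray,
) -> int:
    """Argmax of r^2 with deterministic tie-breaks: smaller beta, then larger
    onset age (smaller duration), then smaller delta."""
    order = np.lexsort((delta_flat, dur_flat, beta_flat, -r2_flat))
    return int(order[0])


def fit_esm_subject(
    observed: np.ndarray,
    C: ConnectivityMatrix,
    epicentres: EpicentreSet,
    age: float,
    grid: ParameterGrid | None = None,
) -> ESMFit:
    """Grid-search (beta, delta, onset) maximizing Pearson r^2 against one
    subject's observed regional pattern.

    A constant observed pattern has no defined correlation; the fit is then
    flagged degenerate with r^2 = 0.
    """
    grid = grid or ParameterGrid()
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (C.n_regions,):
        raise ValueError("observed vector length must match the connectome")
    report = fit_esm_cohort(
        observed[None, :], C, epicentres, np.array([age]), grid
    )
    return report.fits[0]


def fit_esm_cohort(
    observed,
    C: ConnectivityMatrix,
    epicentres: EpicentreSet,
    ages: np.ndarray,
    grid: ParameterGrid | None = None,
    duration_anchor: np.ndarray | None = None,
    duration_window: float = 6.0,
) -> CohortFitReport:
    """Fit every subject against a shared trajectory bank for one epicentre set.

    ``observed`` is a ``(n_subjects, n_regions)`` array (or an object with a
    ``values`` attribute holding one).  The global fit is the Pearson r^2
    between the subject-averaged observed and predicted patterns.

    The model family is invariant under the joint rescaling
    ``(beta, delta, elapsed time) -> (c*beta, c*delta, time/c)`` up to
    higher-order transmission terms, so absolute rates are only weakly
    identified from a single pattern.  When an external estimate of disease
    duration exists (in autosomal-dominant cohorts, the family's expected
    symptom-onset age dates the start of amyloid accumulation),
    ``duration_anchor`` restricts each subject's candidate durations to
    ``anchor +/- duration_window`` years, pinning the time scale.  Subjects
    whose anchored window contains no grid duration fall back to the
    unanchored search.
    """
    grid = grid or ParameterGrid()
    obs = np.asarray(getattr(observed, "values", observed), dtype=float)
    if obs.ndim != 2 or obs.shape[1] != C.n_regions:
        raise ValueError("observed matrix must be (n_subjects, n_regions)")
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != obs.shape[0]:
        raise ValueError("ages must align with observed subjects")
    durations = grid.durations[grid.durations < ages.max()]
    if durations.size == 0:
        raise ValueError("no grid duration is admissible for these ages")
    betas_f, deltas_f, states = _grid_snapshots(C, epicentres, grid, durations)
    n_combo, n_dur, n = states.shape
    flat_states = states.reshape(n_combo * n_dur, n)
    r2 = pearson_r2_matrix(obs, flat_states)  # (S, n_combo*n_dur)
    beta_flat = np.repeat(betas_f, n_dur)
    delta_flat = np.repeat(deltas_f, n_dur)
    dur_flat = np.tile(durations, n_combo)
    fits: list[ESMFit] = []
    predicted = np.empty_like(obs)
    anchor = (
        np.asarray(duration_anchor, dtype=float)
        if duration_anchor is not None
        else None
    )
    for s in range(obs.shape[0]):
        degenerate = np.std(obs[s]) == 0.0
        admissible = dur_flat < ages[s]
        if anchor is not None and np.isfinite(anchor[s]):
            anchored = admissible & (np.abs(dur_flat - anchor[s]) <= duration_window)
            if anchored.any():
                admissible = anchored
        if not admissible.any():
            # subject younger than every grid duration: shortest course only
            admissible = dur_flat == dur_flat.min()
        r2_s = np.where(admissible, r2[s], -np.inf)
        k = _select_best(r2_s, beta_flat, delta_flat, dur_flat)
        params = ESMParameters(
            production_rate=float(beta_flat[k]),
            clearance_rate=float(delta_flat[k]),
            onset_age=float(ages[s] - dur_flat[k]),
            seed_level=grid.seed_level,
        )
        pred = flat_states[k]
        fits.append(
            ESMFit(
                params=params,
                epicentres=epicentres,
                predicted=pred,
                within_subject_r2=0.0 if degenerate else float(r2[s, k]),
                degenerate=bool(degenerate),
            )
        )
        predicted[s] = pred
    mean_within = float(np.mean([f.within_subject_r2 for f in fits]))
    global_r2 = float(
        pearson_r2_matrix(obs.mean(axis=0), predicted.mean(axis=0))[0, 0]
    )
    return CohortFitReport(
        fits=fits,
        mean_within_subject_r2=mean_within,
        global_r2=global_r2,
        predicted=predicted,
        epicentres=epicentres,
    )


def null_model_significance(
    observed_report: CohortFitReport,
    observed,
    epicentres: EpicentreSet,
    ages: np.ndarray,
    nulls: NullEnsemble,
    grid: ParameterGrid | None = None,
) -> NullFitStatistics:
    """Re-fit the cohort against every rewired connectome and summarize.

    Reports the null mean, the 2.5/97.5 percentile interval and the one-sided
    exceedance p-value ``(1 + #{null >= observed}) / (1 + n_null)`` for both
    the global and the mean within-subject fit.
    """
    if nulls.n_null < 1:
        raise ValueError("null ensemble is empty")
    grid = grid or ParameterGrid()
    null_global = np.empty(nulls.n_null)
    null_within = np.empty(nulls.n_null)
    for k, Cn in enumerate(nulls.matrices):
        rep = fit_esm_cohort(observed, Cn, epicentres, ages, grid)
        null_global[k] = rep.global_r2
        null_within[k] = rep.mean_within_subject_r2
    og = observed_report.global_r2
    ow = observed_report.mean_within_subject_r2
    nn = nulls.n_null
    return NullFitStatistics(
        null_global=null_global,
        null_within=null_within,
        global_mean=float(null_global.mean()),
        global_ci=(
            float(np.percentile(null_global, 2.5)),
            float(np.percentile(null_global, 97.5)),
        ),
        within_mean=float(null_within.mean()),
        within_ci=(
            float(np.percentile(null_within, 2.5)),
            float(np.percentile(null_within, 97.5)),
        ),
        p_global=float((1 + np.sum(null_global >= og)) / (1 + nn)),
        p_within=float((1 + np.sum(null_within >= ow)) / (1 + nn)),
        observed_global=og,
        observed_within=ow,
    )
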
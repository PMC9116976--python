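"""Epicentre sweeps, DMN/Striatum/Other subgrouping, longitudinal reliability.

Every bilateral region pair of the atlas (39 candidates for 78 regions) is
tried as the spreading epicentre; a subject's epicentre is the candidate with
the best within-subject fit, and the subject is subgrouped by where that
winner sits: the default-mode set (posterior cingulate, caudal/rostral
anterior cingulate, precuneus, medial orbitofrontal), the striatum (caudate,
putamen), or Other.  Since winner-take-all ignores close runners-up, every
assignment records the r^2 margin to the second-best candidate, and a flag
can mark assignments with margin < 0.01 as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix, bilateral_pairs
from .esm_core import (
    EpicentreSet,
    ParameterGrid,
    fit_esm_cohort,
    pearson_r2_matrix,
)

__all__ = [
    "DMN_REGIONS",
    "STRIATUM_REGIONS",
    "EpicentreAssignment",
    "ReliabilityReport",
    "subgroup_of",
    "candidate_epicentres",
    "sweep_epicentres",
    "sweep_epicentres_cohort",
    "group_epicentre_search",
    "subgroup_frequencies",
    "epicentre_reliability",
]

DMN_REGIONS = frozenset(
    {
        "posterior_cingulate",
        "caudal_anterior_cingulate",
        "rostral_anterior_cingulate",
        "precuneus",
        "medial_orbitofrontal",
    }
)
STRIATUM_REGIONS = frozenset({"caudate", "putamen"})

SUBGROUPS = ("DMN", "Striatum", "Other")


@dataclass
class EpicentreAssignment:
    subject_id: str
    best_epicentre: str  # base region name of the winning bilateral pair
    subgroup: str
    r2_best: float
    margin: float  # r^2 gap to the runner-up candidate
    r2_by_candidate: pd.Series | None = None
    ambiguous: bool | None = None


@dataclass
class ReliabilityReport:
    """T1 vs T2 subgroup confusion and per-cell composite change."""

    confusion: pd.DataFrame  # 3x3 counts, rows = T1 subgroup, cols = T2
    composite_change: pd.DataFrame  # subject_id, t1, t2, delta_composite
    dropped_subjects: list[str] = field(default_factory=list)


def subgroup_of(region_base_name: str) -> str:
    """Pure mapping from a winning epicentre to its phenotype subgroup."""
    name = region_base_name.lower()
    if name in DMN_REGIONS:
        return "DMN"
    if name in STRIATUM_REGIONS:
        return "Striatum"
    return "Other"


def candidate_epicentres(C: ConnectivityMatrix) -> dict[str, EpicentreSet]:
    """All bilateral pairs of the connectome as candidate epicentres,
    keyed and ordered alphabetically by base region name."""
    pairs = bilateral_pairs(C.region_labels)
    out = {}
    for base in sorted(pairs):
        li, ri = pairs[base]
        out[base] = EpicentreSet([C.region_labels[li], C.region_labels[ri]])
    if not out:
        raise ValueError("connectome labels define no bilateral pairs")
    return out


def sweep_epicentres_cohort(
    observed,
    C: ConnectivityMatrix,
    ages: np.ndarray,
    grid: ParameterGrid | None = None,
    candidates: dict[str, EpicentreSet] | None = None,
    subject_ids: list[str] | None = None,
    mark_ambiguous: bool = False,
    ambiguity_margin: float = 0.01,
) -> list[EpicentreAssignment]:
    """Best-epicentre sweep for a whole cohort.

    Parameters are refit per candidate; each candidate's trajectory bank is
    shared across subjects, so the sweep costs one grid integration per
    candidate rather than per subject.  Ties on r^2 break alphabetically by
    candidate name (the candidate dict is ordered).
    """
    grid = grid or ParameterGrid()
    obs = np.asarray(getattr(observed, "values", observed), dtype=float)
    ids = subject_ids or list(
        getattr(observed, "subject_ids", [f"sub-{i:04d}" for i in range(obs.shape[0])])
    )
    candidates = candidates or candidate_epicentres(C)
    names = list(candidates)
    r2_table = np.empty((obs.shape[0], len(names)))
    for j, name in enumerate(names):
        rep = fit_esm_cohort(obs, C, candidates[name], ages, grid)
        r2_table[:, j] = [f.within_subject_r2 for f in rep.fits]
    assignments = []
    for s in range(obs.shape[0]):
        row = r2_table[s]
        best_j = int(np.argmax(row))  # first max = alphabetical tie-break
        runner = np.partition(row, -2)[-2] if row.size > 1 else np.nan
        degenerate = np.std(obs[s]) == 0.0
        margin = float(row[best_j] - runner) if row.size > 1 else float("nan")
        name = "none" if degenerate else names[best_j]
        assignments.append(
            EpicentreAssignment(
                subject_id=str(ids[s]),
                best_epicentre=name,
                subgroup="Other" if degenerate else subgroup_of(name),
                r2_best=0.0 if degenerate else float(row[best_j]),
                margin=margin,
                r2_by_candidate=pd.Series(row, index=names),
                ambiguous=(margin < ambiguity_margin) if mark_ambiguous else None,
            )
        )
    return assignments


def sweep_epicentres(
    observed: np.ndarray,
    C: ConnectivityMatrix,
    age: float,
    grid: ParameterGrid | None = None,
    candidates: dict[str, EpicentreSet] | None = None,
    subject_id: str = "subject",
) -> EpicentreAssignment:
    """Single-subject epicentre sweep (one-row cohort)."""
    return sweep_epicentres_cohort(
        np.asarray(observed, dtype=float)[None, :],
        C,
        np.array([age]),
        grid=grid,
        candidates=candidates,
        subject_ids=[subject_id],
    )[0]


def group_epicentre_search(
    observed,
    C: ConnectivityMatrix,
    ages: np.ndarray,
    grid: ParameterGrid | None = None,
    max_set_size: int = 1,
) -> tuple[EpicentreSet, str, float]:
    """Data-driven group-level epicentre: the bilateral pair (or greedy pair
    of pairs) that best fits the cohort-average pattern.

    Returns (epicentre set, description, global r^2 against the average
    pattern).
    """
    if max_set_size not in (1, 2):
        raise ValueError("max_set_size must be 1 or 2")
    grid = grid or ParameterGrid()
    obs = np.asarray(getattr(observed, "values", observed), dtype=float)
    mean_pattern = obs.mean(axis=0)[None, :]
    mean_age = np.array([float(np.mean(ages))])
    cands = candidate_epicentres(C)
    scores = {}
    for name, epi in cands.items():
        rep = fit_esm_cohort(mean_pattern, C, epi, mean_age, grid)
        scores[name] = rep.fits[0].within_subject_r2
    best = max(sorted(scores), key=lambda k: scores[k])
    best_set, best_name, best_r2 = cands[best], best, scores[best]
    if max_set_size == 2:
        for name, epi in cands.items():
            if name == best:
                continue
            combo = EpicentreSet(cands[best].region_names + epi.region_names)
            rep = fit_esm_cohort(mean_pattern, C, combo, mean_age, grid)
            if rep.fits[0].within_subject_r2 > best_r2:
                best_set = combo
                best_name = f"{best}+{name}"
                best_r2 = rep.fits[0].within_subject_r2
    return best_set, best_name, float(best_r2)


def subgroup_frequencies(
    assignments: list[EpicentreAssignment],
    positive_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Counts and percentages per subgroup, overall and within the
    amyloid-positive subset."""
    groups = [a.subgroup for a in assignments]
    rows = []
    for scope, mask in (
        ("all", np.ones(len(groups), dtype=bool)),
        ("amyloid_positive", np.asarray(positive_mask, dtype=bool)
         if positive_mask is not None else None),
    ):
        if mask is None:
            continue
        sub = [g for g, m in zip(groups, mask) if m]
        total = len(sub)
        for g in SUBGROUPS:
            count = sub.count(g)
            rows.append(
                {
                    "scope": scope,
                    "subgroup": g,
                    "count": count,
                    "percent": 100.0 * count / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


def epicentre_reliability(
    t1: list[EpicentreAssignment],
    t2: list[EpicentreAssignment],
    composites_t1: dict[str, float],
    composites_t2: dict[str, float],
) -> ReliabilityReport:
    """Cross-timepoint subgroup confusion matrix and composite change.

    Subjects are matched by id; unmatched ids are dropped and reported.
    The confusion matrix rows are T1 subgroups, columns T2 subgroups, so each
    row sums to the number of matched subjects with that T1 subgroup.
    """
    a1 = {a.subject_id: a for a in t1}
    a2 = {a.subject_id: a for a in t2}
    common = [sid for sid in a1 if sid in a2]
    dropped = sorted((set(a1) ^ set(a2)))
    confusion = pd.DataFrame(
        0, index=list(SUBGROUPS), columns=list(SUBGROUPS), dtype=int
    )
    rows = []
    for sid in common:
        g1, g2 = a1[sid].subgroup, a2[sid].subgroup
        confusion.loc[g1, g2] += 1
        c1 = composites_t1.get(sid, np.nan)
        c2 = composites_t2.get(sid, np.nan)
        rows.append(
            {
                "subject_id": sid,
                "t1_subgroup": g1,
                "t2_subgroup": g2,
                "delta_composite": c2 - c1,
            }
        )
    return ReliabilityReport(
        confusion=confusion,
        composite_change=pd.DataFrame(rows),
        dropped_subjects=dropped,
    )
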
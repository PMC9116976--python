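"""Subgroup comparison statistics for epicentre phenotypes.

Covers the group-level inference around the epicentre subgroups:
Kolmogorov-Smirnov comparisons of fit distributions, mass-univariate per-ROI
OLS of amyloid signal on subgroup membership (age and sex as covariates) with
Benjamini-Hochberg FDR across regions, Mann-Whitney demographic contrasts
with Bonferroni correction, and a multinomial logistic model of subgroup
membership on sex, CDR, age and education with DMN as the reference category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ROIGlmResult",
    "ks_compare",
    "roi_glm",
    "bh_fdr",
    "subgroup_demographics",
    "multinomial_subgroup_model",
    "PerfectSeparationAdvice",
]

SUBGROUP_ORDER = ["DMN", "Striatum", "Other"]


class PerfectSeparationAdvice(RuntimeError):
    """Multinomial fit failed to converge (e.g. perfect separation);
    advises the ridge-penalized fallback."""


@dataclass
class ROIGlmResult:
    """Per-region subgroup-contrast statistics for one target subgroup."""

    subgroup: str
    region_labels: list[str]
    t_values: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray  # boolean mask at the requested FDR level
    fdr_level: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_labels,
                "t": self.t_values,
                "p": self.p_values,
                "q": self.q_values,
                "significant": self.significant,
            }
        )


def ks_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (sup of ECDF difference).

    Uses the asymptotic two-sample p-value; symmetric in its arguments and
    invariant to common monotone transforms.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q-values, rejection mask)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def _ols_tvals(X: np.ndarray, Y: np.ndarray, col: int) -> tuple[np.ndarray, np.ndarray]:
    """t statistic and two-sided p of coefficient ``col`` for every column of
    Y under one shared design X (mass-univariate OLS)."""
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design matrix")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[col, col])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[col] / se
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return t, p


def roi_glm(
    signal,
    subgroup: np.ndarray,
    covars: pd.DataFrame,
    target: str,
    fdr_level: float = 0.05,
) -> ROIGlmResult:
    """Per-region OLS of amyloid signal on a one-vs-rest subgroup indicator,
    covarying for age and sex, BH-FDR corrected across regions.

    ``signal`` is a subjects x regions array (or object with ``values`` and
    ``region_labels``); ``covars`` must provide ``age`` and ``sex`` columns.
    """
    Y = np.asarray(getattr(signal, "values", signal), dtype=float)
    labels = list(getattr(signal, "region_labels", [f"roi_{i}" for i in range(Y.shape[1])]))
    subgroup = np.asarray(subgroup)
    if len(np.unique(subgroup)) < 2:
        raise ValueError("need at least 2 subgroups for a contrast")
    if target not in set(subgroup):
        raise ValueError(f"target subgroup {target!r} absent from assignments")
    indicator = (subgroup == target).astype(float)
    age = covars["age"].to_numpy(dtype=float)
    sex = pd.Categorical(covars["sex"]).codes.astype(float)
    # constant covariates carry no information and would break the design
    extra = [c for c in (age, sex) if np.std(c) > 0]
    X = np.column_stack([np.ones_like(indicator), indicator, *extra])
    t, p = _ols_tvals(X, Y, col=1)
    qvals, reject = bh_fdr(p, q=fdr_level)
    return ROIGlmResult(
        subgroup=target,
        region_labels=labels,
        t_values=t,
        p_values=p,
        q_values=qvals,
        significant=reject,
        fdr_level=fdr_level,
    )


def subgroup_demographics(
    covars: pd.DataFrame,
    subgroup: np.ndarray,
    variables: tuple[str, ...] = ("age", "eyo"),
) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests on demographic variables across
    subgroups, two-tailed, Bonferroni-corrected over the subgroup pairs.

    Subgroups with fewer than 2 members are skipped; missing variables (e.g.
    EYO in sporadic cohorts) are dropped, never imputed.
    """
    subgroup = np.asarray(subgroup)
    groups = [g for g in SUBGROUP_ORDER if g in set(subgroup)]
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
    n_tests = max(len(pairs), 1)
    rows = []
    for var in variables:
        if var not in covars.columns or covars[var].isna().all():
            continue
        vals = covars[var].to_numpy(dtype=float)
        for a, b in pairs:
            xa = vals[(subgroup == a) & np.isfinite(vals)]
            xb = vals[(subgroup == b) & np.isfinite(vals)]
            if xa.size < 2 or xb.size < 2:
                continue
            u, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            rows.append(
                {
                    "variable": var,
                    "group_a": a,
                    "group_b": b,
                    "U": float(u),
                    "p_raw": float(p),
                    "p_bonferroni": float(min(1.0, p * n_tests)),
                    "median_a": float(np.median(xa)),
                    "median_b": float(np.median(xb)),
                }
            )
    return pd.DataFrame(rows)


def multinomial_subgroup_model(
    subgroup: np.ndarray,
    covars: pd.DataFrame,
    covariates: tuple[str, ...] = ("sex", "cdr", "age", "education"),
    ridge: bool = False,
) -> pd.DataFrame:
    """Multinomial logit of subgroup on covariates, DMN as reference.

    Returns a tidy coefficient table with Wald z statistics for the
    DMN-vs-Striatum and DMN-vs-Other contrasts.  On convergence failure
    (perfect separation) raises :class:`PerfectSeparationAdvice` unless
    ``ridge`` enables a small L2 penalty.
    """
    import statsmodels.api as sm

    subgroup = np.asarray(subgroup)
    present = [g for g in SUBGROUP_ORDER if g in set(subgroup)]
    if len(present) < 3:
        raise ValueError("multinomial model needs all three subgroups present")
    for g in present:
        if np.sum(subgroup == g) < 5:
            raise ValueError(f"subgroup {g!r} has fewer than 5 members")
    cols = []
    for var in covariates:
        v = covars[var]
        cols.append(
            pd.Categorical(v).codes.astype(float)
            if v.dtype == object or str(v.dtype) == "category"
            else v.to_numpy(dtype=float)
        )
    X = sm.add_constant(np.column_stack(cols))
    # code DMN as 0 so it is the reference outcome
    codes = np.array([SUBGROUP_ORDER.index(g) for g in subgroup])
    model = sm.MNLogit(codes, X)
    try:
        if ridge:
            fit = model.fit_regularized(alpha=1.0, disp=False, maxiter=500)
        else:
            fit = model.fit(disp=False, maxiter=500)
        if not ridge and not fit.mle_retvals.get("converged", True):
            raise PerfectSeparationAdvice(
                "multinomial fit did not converge (possible perfect "
                "separation); retry with ridge=True"
            )
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise PerfectSeparationAdvice(
            f"multinomial fit failed ({exc}); retry with ridge=True"
        ) from exc
    names = ["const", *covariates]
    params = np.asarray(fit.params)
    bse = np.asarray(fit.bse)
    rows = []
    for j, contrast in enumerate(("Striatum", "Other")):
        for i, name in enumerate(names):
            se = bse[i, j]
            coef = params[i, j]
            z = coef / se if se > 0 else np.nan
            rows.append(
                {
                    "contrast": f"DMN_vs_{contrast}",
                    "covariate": name,
                    "coef": float(coef),
                    "se": float(se),
                    "z": float(z),
                    "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan,
                }
            )
    return pd.DataFrame(rows)
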
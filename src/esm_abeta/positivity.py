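"""Data-driven amyloid positivity: composite value, GMM cutoff, dual rule.

Amyloid burden is summarized as the unweighted mean over a composite of
AD-vulnerable cortical regions (bilateral precuneus, superior frontal,
rostral middle frontal, lateral/medial orbitofrontal, superior/middle
temporal).  A two-component univariate Gaussian mixture fitted over the whole
cohort (controls included) separates the amyloid-negative and -positive
modes; the cutoff is the point between the component means where the weighted
component densities are equal (the posterior-0.5 crossing).  A subject is
called positive only when it surpasses the cutoff on BOTH the SUVR and the
deposition-probability composite (strict inequality).  Thresholds fitted on
one cohort transfer to another as plain parameters, with no refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "CompositeDefinition",
    "PositivityThresholds",
    "ThresholdMethod",
    "composite_value",
    "fit_gmm_cutoff",
    "classify_positivity",
    "DegenerateMixtureError",
]

_DEFAULT_COMPOSITE = [
    "precuneus",
    "superior_frontal",
    "rostral_middle_frontal",
    "lateral_orbitofrontal",
    "medial_orbitofrontal",
    "superior_temporal",
    "middle_temporal",
]


class ThresholdMethod(str, Enum):
    GMM = "gmm"
    FIXED = "fixed"


class DegenerateMixtureError(RuntimeError):
    """Raised when the two-component fit collapses; advises a fixed cutoff."""


@dataclass
class CompositeDefinition:
    """Base names of the bilateral composite regions."""

    region_names: list[str] = field(default_factory=lambda: list(_DEFAULT_COMPOSITE))

    def columns(self, region_labels: list[str]) -> list[int]:
        """Indices of all (left + right) columns matching the composite,
        case-insensitive on the base name after the hemisphere prefix."""
        wanted = {r.lower() for r in self.region_names}
        cols = []
        for i, lab in enumerate(region_labels):
            head, _, base = lab.partition("_")
            base = base.lower() if head.upper() in ("L", "R") else lab.lower()
            if base in wanted:
                cols.append(i)
        found = set()
        for i in cols:
            head, _, base = region_labels[i].partition("_")
            found.add(base.lower() if head.upper() in ("L", "R") else region_labels[i].lower())
        missing = sorted(wanted - found)
        if missing:
            raise KeyError(f"composite regions {missing} not found in labels")
        return cols


@dataclass
class GMMParams:
    means: tuple[float, float]
    variances: tuple[float, float]
    weights: tuple[float, float]


@dataclass
class PositivityThresholds:
    suvr_cutoff: float
    probability_cutoff: float
    method: ThresholdMethod = ThresholdMethod.GMM
    suvr_gmm: GMMParams | None = None
    probability_gmm: GMMParams | None = None
    seed: int = 0


def composite_value(row: np.ndarray, region_labels: list[str],
                    composite: CompositeDefinition | None = None) -> float:
    """Unweighted mean over the composite's bilateral columns.

    Missing (NaN) values in any composite region raise rather than being
    silently averaged over.
    """
    composite = composite or CompositeDefinition()
    row = np.asarray(row, dtype=float)
    cols = composite.columns(region_labels)
    vals = row[cols]
    if np.any(~np.isfinite(vals)):
        bad = [region_labels[c] for c, v in zip(cols, vals) if not np.isfinite(v)]
        raise ValueError(f"missing composite values in {bad}")
    return float(vals.mean())


def _equal_density_crossing(w, mu, var) -> float:
    """Root of w1*phi1(x) = w2*phi2(x) between the two component means."""
    lo, hi = sorted(mu)

    def f(x):
        return (np.log(w[0]) + stats.norm.logpdf(x, mu[0], np.sqrt(var[0]))
                - np.log(w[1]) - stats.norm.logpdf(x, mu[1], np.sqrt(var[1])))

    if f(lo) * f(hi) > 0:
        raise DegenerateMixtureError(
            "no posterior-0.5 crossing between component means; "
            "components overlap too much — use a fixed threshold"
        )
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def fit_gmm_cutoff(values: np.ndarray, seed: int = 0) -> tuple[float, GMMParams]:
    """Fit a two-component Gaussian mixture and return its equal-density cutoff.

    Multiple EM restarts with a fixed seed keep the result deterministic.
    A component weight below 0.02 or a collapsed variance is treated as a
    degenerate fit.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise ValueError("need at least 10 observations to fit a mixture")
    if np.any(~np.isfinite(x)):
        raise ValueError("mixture input contains non-finite values")
    # random-from-data restarts outperform k-means initialization when one
    # mode is a narrow spike next to a broad mode (the amyloid-negative
    # cluster); the best-likelihood fit across restarts is kept
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=20,
        init_params="random_from_data", random_state=int(seed), reg_covar=1e-9,
    ).fit(x[:, None])
    mu = gm.means_.ravel()
    var = gm.covariances_.ravel()
    w = gm.weights_.ravel()
    order = np.argsort(mu)
    mu, var, w = mu[order], var[order], w[order]
    span = x.max() - x.min()
    separation = mu[1] - mu[0]
    if (
        w.min() < 0.02
        or var.min() < (1e-6 * max(span, 1e-12)) ** 2
        or separation < 2.0 * np.sqrt(var.min())
    ):
        raise DegenerateMixtureError(
            "degenerate mixture (vanishing weight, collapsed variance or "
            "unseparated components); use a fixed threshold instead"
        )
    cutoff = _equal_density_crossing(w, mu, var)
    params = GMMParams(
        means=(float(mu[0]), float(mu[1])),
        variances=(float(var[0]), float(var[1])),
        weights=(float(w[0]), float(w[1])),
    )
    return cutoff, params


def classify_positivity(
    composite_suvr: float,
    composite_prob: float,
    thresholds: PositivityThresholds,
) -> bool:
    """Dual-metric rule: positive iff strictly above BOTH cutoffs."""
    return bool(
        composite_suvr > thresholds.suvr_cutoff
        and composite_prob > thresholds.probability_cutoff
    )
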
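"""ROC/AUC risk discrimination and the familial all-predisposition benchmark.

With population log-RR ~ N(mu, sigma2) and case log-RR ~ N(mu + sigma2,
sigma2), a risk threshold t classifies everyone above it as high risk:

    FPR(t) = 1 - Phi((t - mu) / sigma)
    TPR(t) = 1 - Phi((t - mu - sigma2) / sigma)

This is the equal-variance binormal ROC; its exact area is Phi(sigma /
sqrt(2)). The curve is generated on a finite, even threshold grid over
mu +/- 3*sigma2 and integrated over the computed points only (no
extrapolation to the (0,0)/(1,1) corners), which is the replication mode
for the published AUC; the analytic value is also exposed.

The familial benchmark converts a sibling recurrence risk lambda into a
log-normal model for *all* predisposition (genetic plus shared
environment) via sigma2 = 2 * ln(lambda), the multiplicative polygenic
relation in which siblings share half of the log-risk variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .prs_model import PolygenicModel

__all__ = [
    "RocCurve",
    "FamilialModel",
    "roc_curve",
    "auc",
    "case_fraction_above_percentile",
    "familial_model",
]


@dataclass(frozen=True)
class RocCurve:
    """Ordered ROC points with the threshold grid that generated them."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    sigma2: float
    truncated: bool = True


@dataclass(frozen=True)
class FamilialModel:
    """All-predisposition risk model derived from a sibling recurrence risk."""

    lambda_sibling: float
    model: PolygenicModel = field(init=False)

    def __post_init__(self) -> None:
        if self.lambda_sibling < 1.0:
            raise ValueError(
                f"lambda_sibling must be >= 1, got {self.lambda_sibling}"
            )
        sigma2 = 2.0 * math.log(self.lambda_sibling)
        object.__setattr__(
            self,
            "model",
            PolygenicModel(mu=-sigma2 / 2.0, sigma2=sigma2, source="familial_lambda"),
        )


def roc_curve(model: PolygenicModel, n_thresholds: int = 1201) -> RocCurve:
    """ROC points on an even threshold grid over [mu - 3*sigma2, mu + 3*sigma2].

    Note the grid half-width is 3*sigma2 (three variances, not three
    standard deviations). Thresholds run low to high, so FPR and TPR both
    decrease along the grid.
    """
    if model.sigma2 <= 0.0:
        raise ValueError("ROC undefined for sigma2 = 0 (no discrimination)")
    if n_thresholds < 3:
        raise ValueError(f"n_thresholds must be >= 3, got {n_thresholds}")
    t = np.linspace(model.mu - 3.0 * model.sigma2, model.mu + 3.0 * model.sigma2,
                    n_thresholds)
    fpr = 1.0 - norm.cdf((t - model.mu) / model.sigma)
    tpr = 1.0 - norm.cdf((t - model.mu - model.sigma2) / model.sigma)
    return RocCurve(thresholds=t, fpr=fpr, tpr=tpr, sigma2=model.sigma2)


def auc(curve, method: str = "trapezoid_truncated") -> float:
    """Area under the ROC curve.

    Parameters
    ----------
    curve : RocCurve or PolygenicModel
        A computed curve; the ``analytic`` method also accepts a model
        directly (defined even at sigma2 = 0, where it returns 0.5).
    method : {"trapezoid_truncated", "trapezoid_full", "analytic"}
        ``trapezoid_truncated`` integrates the polyline over the computed
        points only. ``trapezoid_full`` appends the (0,0) and (1,1)
        corners before integrating. ``analytic`` returns the exact
        binormal area Phi(sigma / sqrt(2)).
    """
    if method == "analytic":
        sigma2 = curve.sigma2
        return float(norm.cdf(math.sqrt(sigma2) / math.sqrt(2.0)))
    if not isinstance(curve, RocCurve):
        raise TypeError("trapezoid methods require a RocCurve")
    if curve.fpr.size < 2:
        raise ValueError("need at least 2 ROC points to integrate")
    order = np.argsort(curve.fpr)
    x, y = curve.fpr[order], curve.tpr[order]
    if method == "trapezoid_full":
        x = np.concatenate([[0.0], x, [1.0]])
        y = np.concatenate([[0.0], y, [1.0]])
    elif method != "trapezoid_truncated":
        raise ValueError(f"unknown method {method!r}")
    return float(np.trapezoid(y, x))


def case_fraction_above_percentile(model: PolygenicModel, q: float) -> float:
    """Fraction of cases whose PRS exceeds the population q-quantile.

    Equals 1 - Phi(z_q - sigma); always at least 1 - q, with equality only
    when sigma2 = 0.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"percentile q must be in (0, 1), got {q}")
    return float(1.0 - norm.cdf(norm.ppf(q) - model.sigma))


def familial_model(lambda_sibling: float) -> FamilialModel:
    """Build the all-predisposition model from a sibling recurrence risk."""
    return FamilialModel(lambda_sibling=lambda_sibling)
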
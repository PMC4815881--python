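"""Liability-threshold conversion from common-SNP heritability to polygenic variance.

The chain reconstructed here: an array-based heritability estimate h2 on
the liability scale is converted to a sibling recurrence risk lambda_s
under the liability-threshold model (siblings share half the additive
liability, correlation rho = h2/2); lambda_s maps to the variance of the
log-normal relative-risk model via sigma2 = 2*ln(lambda_s); and a
partial-discovery scenario scales that variance by the fraction of loci
assumed discovered (variance is additive over exchangeable loci). The
published improved scenario (top-1% relative risk 19.2) is approximately
recovered by h2 = 0.37, prevalence 0.005 and a discovered fraction of
one half, but the chain is a documented reconstruction, not a published
derivation, and the screening module consumes 19.2 as a fixed input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import multivariate_normal, norm

__all__ = [
    "LiabilityParams",
    "sibling_recurrence_from_h2",
    "sigma2_from_lambda",
    "improved_sigma2",
    "improved_variance_chain",
]


@dataclass(frozen=True)
class LiabilityParams:
    """Heritability of liability and disease prevalence.

    h2_liability is the proportion of liability variance that is additive
    genetic; full siblings then share rho = h2/2 of it (no dominance, no
    shared environment).
    """

    h2_liability: float
    prevalence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_liability <= 1.0:
            raise ValueError(f"h2_liability must be in [0, 1], got {self.h2_liability}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0, 1), got {self.prevalence}")

    @property
    def sibling_correlation(self) -> float:
        return self.h2_liability / 2.0


def sibling_recurrence_from_h2(params: LiabilityParams) -> float:
    """Sibling recurrence relative risk under the liability-threshold model.

    Disease occurs when standard-normal liability exceeds
    T = Phi^{-1}(1 - K) for prevalence K. With sibling liability
    correlation rho = h2/2,

        lambda_s = P(L_sib > T, L_proband > T) / K^2,

    the bivariate-normal upper tail rescaled by the marginal risks.
    Returns exactly 1 when h2 = 0.
    """
    K = params.prevalence
    rho = params.sibling_correlation
    if rho == 0.0:
        return 1.0
    T = norm.ppf(1.0 - K)
    bvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    # upper tail by inclusion-exclusion from the joint CDF
    joint = 1.0 - 2.0 * norm.cdf(T) + bvn.cdf([T, T])
    return float(joint / K**2)


def sigma2_from_lambda(lambda_s: float) -> float:
    """Log-normal RR variance implied by a sibling recurrence risk: 2*ln(lambda)."""
    if lambda_s < 1.0:
        raise ValueError(f"lambda_s must be >= 1, got {lambda_s}")
    return 2.0 * math.log(lambda_s)


def improved_sigma2(sigma2_common: float, discovered_fraction: float) -> float:
    """Variance captured when only a fraction of exchangeable loci are discovered."""
    if sigma2_common < 0.0:
        raise ValueError("sigma2_common must be >= 0")
    if not 0.0 <= discovered_fraction <= 1.0:
        raise ValueError(
            f"discovered_fraction must be in [0, 1], got {discovered_fraction}"
        )
    return sigma2_common * discovered_fraction


def improved_variance_chain(
    h2: float, prevalence: float, discovered_fraction: float
) -> dict:
    """Full h2 -> lambda_s -> sigma2 -> partial-discovery chain, as a dict.

    Includes the midpoint-percentile relative risk for the top 1% under
    the partial-discovery variance, the quantity the improved screening
    scenario parameterises.
    """
    params = LiabilityParams(h2_liability=h2, prevalence=prevalence)
    lambda_s = sibling_recurrence_from_h2(params)
    sigma2_common = sigma2_from_lambda(lambda_s)
    sigma2_partial = improved_sigma2(sigma2_common, discovered_fraction)
    rr_top1 = float(math.exp(norm.ppf(0.995) * math.sqrt(sigma2_partial)))
    return {
        "h2_liability": h2,
        "prevalence": prevalence,
        "discovered_fraction": discovered_fraction,
        "lambda_s": lambda_s,
        "sigma2_common": sigma2_common,
        "sigma2_improved": sigma2_partial,
        "rr_top1_midpoint": rr_top1,
    }
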
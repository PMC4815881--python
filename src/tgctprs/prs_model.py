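"""Log-normal polygenic relative-risk model for TGCT built from a SNP panel.

The polygenic risk score (PRS) of an individual is the sum of risk-allele
counts weighted by per-allele log odds ratios,

    PRS = sum_n  beta_n * x_n,      beta_n = ln(OR_n),  x_n in {0, 1, 2}.

Treating the loci as independent and in Hardy-Weinberg equilibrium, the PRS
is approximately normal with variance

    sigma^2 = sum_n  2 * p_n * (1 - p_n) * beta_n^2,

so relative risk (RR) is log-normally distributed in the population,
RR ~ LN(mu, sigma^2). The population mean RR is normalised to 1 by setting
mu = -sigma^2 / 2. In cases the log-RR distribution is shifted right by
sigma^2 (same variance), the standard result for a multiplicative rare
disease model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SNPLocus",
    "PolygenicModel",
    "load_snp_panel",
    "locus_log_rr",
    "locus_variance",
    "build_model",
    "model_summary",
    "prs_of_genotype",
    "rr_at_percentile",
    "tail_average_rr",
    "absolute_lifetime_risk",
    "case_distribution",
]

PANEL_COLUMNS = ("snp_id", "risk_allele_freq", "per_allele_or")


@dataclass(frozen=True)
class SNPLocus:
    """One susceptibility variant.

    Parameters
    ----------
    snp_id : str
        Variant identifier (non-empty; unique within a panel).
    risk_allele_freq : float
        Population frequency of the risk allele, strictly inside (0, 1).
    per_allele_or : float
        Per-allele odds ratio, treated as a per-allele relative risk
        (rare-disease approximation); must be positive.
    """

    snp_id: str
    risk_allele_freq: float
    per_allele_or: float

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if not 0.0 < self.risk_allele_freq < 1.0:
            raise ValueError(
                f"{self.snp_id}: risk_allele_freq must be in (0, 1), "
                f"got {self.risk_allele_freq}"
            )
        if not self.per_allele_or > 0.0:
            raise ValueError(
                f"{self.snp_id}: per_allele_or must be > 0, got {self.per_allele_or}"
            )


@dataclass(frozen=True)
class PolygenicModel:
    """Log-normal relative-risk model LN(mu, sigma2).

    ``source`` records how the variance was obtained: summed from a SNP
    panel (``snp_panel``), derived from a sibling recurrence risk
    (``familial_lambda``), or supplied directly (``explicit``).
    """

    mu: float
    sigma2: float
    source: str = "explicit"

    _SOURCES = ("snp_panel", "familial_lambda", "explicit")

    def __post_init__(self) -> None:
        if self.sigma2 < 0.0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if self.source not in self._SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "snp_panel" and not math.isclose(
            self.mu, -self.sigma2 / 2.0, rel_tol=0.0, abs_tol=1e-12
        ):
            raise ValueError("snp_panel models require mu = -sigma2/2")

    @property
    def sigma(self) -> float:
        """Standard deviation of log relative risk."""
        return math.sqrt(self.sigma2)

    @property
    def mean_rr(self) -> float:
        """Population mean relative risk, exp(mu + sigma2/2)."""
        return math.exp(self.mu + self.sigma2 / 2.0)


def load_snp_panel(table_source) -> list[SNPLocus]:
    """Read a SNP panel from a tab-separated table.

    Parameters
    ----------
    table_source : path, file-like or pandas.DataFrame
        Must provide columns ``snp_id``, ``risk_allele_freq`` and
        ``per_allele_or``; ``#`` lines are comments.

    Returns
    -------
    list of SNPLocus
        Loci in file order.

    Raises
    ------
    ValueError
        On a frequency outside (0, 1), a non-positive odds ratio
        (the message names the offending row) or a duplicated snp_id.
    """
    if isinstance(table_source, pd.DataFrame):
        table = table_source
    else:
        table = pd.read_csv(table_source, sep="\t", comment="#")
    missing = [c for c in PANEL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"panel table is missing columns: {missing}")

    loci: list[SNPLocus] = []
    seen: set[str] = set()
    for _, row in table.iterrows():
        snp_id = str(row["snp_id"])
        if snp_id in seen:
            raise ValueError(f"duplicate snp_id in panel: {snp_id}")
        seen.add(snp_id)
        loci.append(
            SNPLocus(
                snp_id=snp_id,
                risk_allele_freq=float(row["risk_allele_freq"]),
                per_allele_or=float(row["per_allele_or"]),
            )
        )
    return loci


def locus_log_rr(locus: SNPLocus) -> float:
    """Per-allele log relative risk, beta = ln(OR)."""
    return math.log(locus.per_allele_or)


def locus_variance(locus: SNPLocus) -> float:
    """Contribution of one locus to the log-RR variance: 2*p*(1-p)*ln(OR)^2.

    This is the variance of beta * x for x ~ Binomial(2, p) under
    Hardy-Weinberg equilibrium.
    """
    p = locus.risk_allele_freq
    return 2.0 * p * (1.0 - p) * locus_log_rr(locus) ** 2


def build_model(panel: Iterable[SNPLocus]) -> PolygenicModel:
    """Build the population log-normal RR model from a SNP panel.

    sigma2 is the sum of per-locus variances; mu = -sigma2/2 so that the
    population mean RR equals 1.
    """
    loci = list(panel)
    if not loci:
        raise ValueError("cannot build a model from an empty panel")
    sigma2 = sum(locus_variance(locus) for locus in loci)
    return PolygenicModel(mu=-sigma2 / 2.0, sigma2=sigma2, source="snp_panel")


def model_summary(panel: Iterable[SNPLocus]) -> dict:
    """JSON-serialisable summary: mu, sigma2, n_loci, per-locus variances."""
    loci = list(panel)
    model = build_model(loci)
    return {
        "mu": model.mu,
        "sigma2": model.sigma2,
        "n_loci": len(loci),
        "per_locus_variances": {l.snp_id: locus_variance(l) for l in loci},
    }


def prs_of_genotype(panel: Sequence[SNPLocus], genotype: Sequence[int]) -> float:
    """Polygenic risk score (log scale) of one genotype vector.

    ``genotype`` holds risk-allele counts in {0, 1, 2}, aligned to the
    panel order.
    """
    counts = np.asarray(genotype)
    if counts.shape != (len(panel),):
        raise ValueError(
            f"genotype length {counts.shape} does not match panel size {len(panel)}"
        )
    if not np.isin(counts, (0, 1, 2)).all():
        raise ValueError("genotype entries must be 0, 1 or 2")
    betas = np.array([locus_log_rr(l) for l in panel])
    return float(betas @ counts)


def rr_at_percentile(model: PolygenicModel, q: float) -> float:
    """Relative risk at population percentile ``q``, versus the median.

    Under LN(mu, sigma2) the q-quantile of RR divided by the median
    exp(mu) is exp(z_q * sigma); it equals 1 exactly at q = 0.5.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"percentile q must be in (0, 1), got {q}")
    return float(np.exp(norm.ppf(q) * model.sigma))


def tail_average_rr(
    model: PolygenicModel,
    top_fraction: float,
    convention: str = "midpoint_percentile",
) -> float:
    """Average relative risk in the top ``top_fraction`` of the distribution.

    Two conventions are offered:

    ``midpoint_percentile``
        The RR at the midpoint percentile of the tail, i.e. at
        1 - top_fraction/2 (e.g. the 99.5th centile for the top 1%). This
        is the convention behind the headline per-centile figures.
    ``truncated_mean``
        The exact mean of the log-normal RR above the (1 - top_fraction)
        population quantile, divided by the median:
        exp(sigma2/2) * Phi(sigma - z_{1-f}) / f. Always at least as large
        as the midpoint value because the log-normal is right-skewed.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError(f"top_fraction must be in (0, 1), got {top_fraction}")
    if convention == "midpoint_percentile":
        return rr_at_percentile(model, 1.0 - top_fraction / 2.0)
    if convention == "truncated_mean":
        z = norm.ppf(1.0 - top_fraction)
        return float(
            np.exp(model.sigma2 / 2.0) * norm.cdf(model.sigma - z) / top_fraction
        )
    raise ValueError(f"unknown convention {convention!r}")


def absolute_lifetime_risk(rr: float, baseline_risk: float) -> float:
    """Absolute lifetime risk: rr * baseline, capped at 1."""
    if rr < 0.0:
        raise ValueError(f"rr must be >= 0, got {rr}")
    if not 0.0 <= baseline_risk <= 1.0:
        raise ValueError(f"baseline_risk must be in [0, 1], got {baseline_risk}")
    return min(rr * baseline_risk, 1.0)


def case_distribution(model: PolygenicModel) -> PolygenicModel:
    """Log-RR distribution among cases: LN(mu + sigma2, sigma2).

    The case distribution keeps the population variance but its mean is
    shifted right by sigma2, so the mean case RR exceeds the population
    mean RR by a factor exp(sigma2).
    """
    return PolygenicModel(
        mu=model.mu + model.sigma2, sigma2=model.sigma2, source="explicit"
    )
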
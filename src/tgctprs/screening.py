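"""Deterministic expected-value simulation of multi-stage TGCT screening.

Cascades over a population of men:

* two-stage  — genotype everyone, biopsy the top PRS stratum;
* three-stage — insert a non-invasive semen CIS assay between genotyping
  and biopsy, so only assay-positive men are biopsied;
* improved   — the three-stage cascade under a strengthened risk model
  (top-1% relative risk 19.2) and a better semen assay (sensitivity 80%).

All arithmetic is expected-value (no sampling). The three-stage cascade
has two modes. ``coherent`` propagates each test's sensitivity once:
detected = cases * semen_sens * biopsy_sens. ``paper_replication``
reproduces the published chain, which builds on the *rounded* two-stage
detection count and therefore applies biopsy sensitivity twice:
detected = round(cases * biopsy_sens) * semen_sens * biopsy_sens. Only
the replication chain reproduces the published three-stage counts; only
the coherent chain is used for the improved scenario. See
docs/methods.md for the full account.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ScreeningAssumptions",
    "ScreeningOutcome",
    "run_two_stage",
    "run_three_stage",
    "run_improved",
    "format_report",
    "round_half_away",
    "SCENARIO_PRESETS",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (448.5 -> 449), unlike banker's rounding.

    The input is first snapped to 9 decimals so that expected-value chains
    landing on an exact .5 boundary (e.g. 10000*0.005*9.2*0.975 = 448.5)
    are not pushed below it by binary representation error.
    """
    scale = 10.0 ** ndigits
    snapped = round(abs(x) * scale, 9)
    return math.copysign(math.floor(snapped + 0.5), x) / scale


_PROB_FIELDS = (
    "lifetime_risk", "mortality_rate", "chemo_rate", "biopsy_sensitivity",
    "biopsy_complication_rate", "semen_sensitivity", "semen_specificity",
    "uptake", "top_fraction", "residual_risk_after_orchidectomy",
)


@dataclass(frozen=True)
class ScreeningAssumptions:
    """Clinical and design parameters of one screening cascade.

    Defaults are the baseline assumptions: lifetime TGCT risk 0.5%,
    mortality 2.8% of cases, chemotherapy in 65% of cases, biopsy
    sensitivity 97.5% with a 2.8% complication rate, semen assay
    sensitivity 67% / specificity 98%, full uptake, and follow-up of the
    top 1% of the PRS distribution whose average relative risk is 9.2.
    ``tail_rr`` is taken at printed precision (9.2 / 19.2) rather than
    recomputed, because the cascade arithmetic is defined on the rounded
    value.
    """

    population_size: int = 1_000_000
    lifetime_risk: float = 0.005
    mortality_rate: float = 0.028
    chemo_rate: float = 0.65
    biopsy_sensitivity: float = 0.975
    biopsy_complication_rate: float = 0.028
    semen_sensitivity: float = 0.67
    semen_specificity: float = 0.98
    uptake: float = 1.0
    top_fraction: float = 0.01
    tail_rr: float = 9.2
    residual_risk_after_orchidectomy: float = 0.0

    def __post_init__(self) -> None:
        if self.population_size <= 0:
            raise ValueError("population_size must be positive")
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tail_rr <= 0.0:
            raise ValueError(f"tail_rr must be positive, got {self.tail_rr}")
        if self.tail_rr * self.lifetime_risk > 1.0:
            raise ValueError(
                "tail_rr * lifetime_risk exceeds 1: the stratum risk is not a "
                "probability"
            )


SCENARIO_PRESETS: dict[str, ScreeningAssumptions] = {
    "two_stage": ScreeningAssumptions(),
    "three_stage": ScreeningAssumptions(),
    "improved": replace(ScreeningAssumptions(), tail_rr=19.2, semen_sensitivity=0.80),
}


@dataclass(frozen=True)
class ScreeningOutcome:
    """Expected counts and rates from one cascade (unrounded)."""

    scenario: str
    mode: str
    n_genotyped: float
    n_second_stage: float
    n_semen_tests: float
    n_biopsies: float
    expected_true_cases_in_stratum: float
    n_detected: float
    n_deaths_prevented: float
    n_chemo_avoided: float
    n_biopsy_complications: float
    ppv_stage1: float
    ppv_noninvasive: float | None
    npv_stage1: float
    fraction_of_population_cases_detected: float


def _stage1(a: ScreeningAssumptions) -> tuple[float, float, float, float]:
    """Common genotyping stage: cohort sizes and case expectations."""
    n_genotyped = a.population_size * a.uptake
    n_second_stage = a.population_size * a.top_fraction * a.uptake
    total_cases = a.population_size * a.lifetime_risk
    expected_true_cases = n_second_stage * a.lifetime_risk * a.tail_rr
    return n_genotyped, n_second_stage, total_cases, expected_true_cases


def _npv_stage1(a: ScreeningAssumptions, n_second_stage: float,
                total_cases: float, expected_true_cases: float) -> float:
    below = a.population_size - n_second_stage
    if below <= 0:
        return 1.0
    return 1.0 - (total_cases - expected_true_cases) / below


def run_two_stage(a: ScreeningAssumptions) -> ScreeningOutcome:
    """Genotype the population; biopsy every man in the top PRS stratum."""
    n_genotyped, n_second, total_cases, true_cases = _stage1(a)
    n_detected = true_cases * a.biopsy_sensitivity
    prevented = n_detected * (1.0 - a.residual_risk_after_orchidectomy)
    return ScreeningOutcome(
        scenario="two_stage",
        mode="coherent",
        n_genotyped=n_genotyped,
        n_second_stage=n_second,
        n_semen_tests=0.0,
        n_biopsies=n_second,
        expected_true_cases_in_stratum=true_cases,
        n_detected=n_detected,
        n_deaths_prevented=prevented * a.mortality_rate,
        n_chemo_avoided=prevented * a.chemo_rate,
        n_biopsy_complications=n_second * a.biopsy_complication_rate,
        ppv_stage1=n_detected / n_second if n_second else 0.0,
        ppv_noninvasive=None,
        npv_stage1=_npv_stage1(a, n_second, total_cases, true_cases),
        fraction_of_population_cases_detected=(
            n_detected / total_cases if total_cases else 0.0
        ),
    )


def run_three_stage(a: ScreeningAssumptions, mode: str = "coherent") -> ScreeningOutcome:
    """Genotype, triage the top stratum by semen assay, biopsy assay-positives.

    Semen true positives TP = cases_in_stratum * semen_sensitivity; false
    positives FP = non_cases * (1 - semen_specificity); biopsies = TP + FP.

    In ``coherent`` mode, detected = TP * biopsy_sensitivity. In
    ``paper_replication`` mode, detected chains off the rounded two-stage
    count — round(cases * biopsy_sens) * semen_sens * biopsy_sens — and the
    non-invasive PPV is reported as the rounded detection count over the
    biopsies, matching the published arithmetic; in this mode the identity
    ppv * biopsies = detected holds only approximately.
    """
    if mode not in ("coherent", "paper_replication"):
        raise ValueError(f"unknown mode {mode!r}")
    n_genotyped, n_second, total_cases, true_cases = _stage1(a)
    tp = true_cases * a.semen_sensitivity
    fp = (n_second - true_cases) * (1.0 - a.semen_specificity)
    n_biopsies = tp + fp
    if mode == "coherent":
        n_detected = tp * a.biopsy_sensitivity
        ppv_noninv = n_detected / n_biopsies if n_biopsies else 0.0
    else:
        two_stage_count = round_half_away(true_cases * a.biopsy_sensitivity)
        n_detected = two_stage_count * a.semen_sensitivity * a.biopsy_sensitivity
        ppv_noninv = (
            round_half_away(n_detected) / n_biopsies if n_biopsies else 0.0
        )
    prevented = n_detected * (1.0 - a.residual_risk_after_orchidectomy)
    return ScreeningOutcome(
        scenario="three_stage",
        mode=mode,
        n_genotyped=n_genotyped,
        n_second_stage=n_second,
        n_semen_tests=n_second,
        n_biopsies=n_biopsies,
        expected_true_cases_in_stratum=true_cases,
        n_detected=n_detected,
        n_deaths_prevented=prevented * a.mortality_rate,
        n_chemo_avoided=prevented * a.chemo_rate,
        n_biopsy_complications=n_biopsies * a.biopsy_complication_rate,
        ppv_stage1=(true_cases * a.biopsy_sensitivity) / n_second if n_second else 0.0,
        ppv_noninvasive=ppv_noninv,
        npv_stage1=_npv_stage1(a, n_second, total_cases, true_cases),
        fraction_of_population_cases_detected=(
            n_detected / total_cases if total_cases else 0.0
        ),
    )


def run_improved(a: ScreeningAssumptions | None = None) -> ScreeningOutcome:
    """Three-stage cascade under the improved model, always in coherent mode.

    Defaults to the improved preset: top-1% relative risk 19.2 and semen
    assay sensitivity 80%, all other assumptions at baseline.
    """
    if a is None:
        a = SCENARIO_PRESETS["improved"]
    out = run_three_stage(a, mode="coherent")
    return replace(out, scenario="improved")


_COUNT_FIELDS = (
    "n_genotyped", "n_second_stage", "n_semen_tests", "n_biopsies",
    "expected_true_cases_in_stratum", "n_detected", "n_deaths_prevented",
    "n_chemo_avoided", "n_biopsy_complications",
)
_RATE_FIELDS = (
    "ppv_stage1", "ppv_noninvasive", "npv_stage1",
    "fraction_of_population_cases_detected",
)


def format_report(outcome: ScreeningOutcome, rate_dp: int = 1) -> dict:
    """Presentation report: integer counts, percent rates, plus raw values.

    Counts round half away from zero; rates are percentages at ``rate_dp``
    decimals. The unrounded values ride along under ``"raw"`` so nothing
    downstream ever depends on display rounding.
    """
    display: dict[str, str] = {}
    raw: dict[str, float | str | None] = {
        "scenario": outcome.scenario, "mode": outcome.mode,
    }
    for name in _COUNT_FIELDS:
        v = getattr(outcome, name)
        raw[name] = v
        display[name] = f"{int(round_half_away(v)):d}"
    for name in _RATE_FIELDS:
        v = getattr(outcome, name)
        raw[name] = v
        if v is None:
            display[name] = "n/a"
        else:
            display[name] = f"{round_half_away(100.0 * v, rate_dp):.{rate_dp}f}%"
    return {"raw": raw, "display": display}
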
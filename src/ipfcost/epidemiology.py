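"""Case counting, diagnosis annualization ratio, and DEALE mortality.

The DEALE (declining exponential approximation to life expectancy) gives
the annual mortality rate as the reciprocal of remaining life expectancy:
``12 / median_survival_months``, capped at 1.  The plain reciprocal — not
``1 - exp(-mu)`` — is used deliberately: it is the convention the model is
calibrated to (survivals of 66 / 42 / 15 months map to annual mortality of
18.2 % / 28.6 % / 80 % at one-decimal rounding).

Case counts are kept unrounded internally; integer rounding (half-up) is a
reporting concern only, exposed via :class:`CaseCounts` properties.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .model_io import EpidemiologySpec
from .rounding import round_half_up_int

__all__ = [
    "CaseCounts",
    "prevalent_cases",
    "diagnosed_cases",
    "case_counts",
    "annualization_ratio",
    "deale_annual_mortality",
]


@dataclass(frozen=True)
class CaseCounts:
    """Unrounded prevalent/diagnosed case counts with reporting accessors."""

    prevalent: float
    diagnosed: float

    @property
    def prevalent_reported(self) -> int:
        return round_half_up_int(self.prevalent)

    @property
    def diagnosed_reported(self) -> int:
        return round_half_up_int(self.diagnosed)


def prevalent_cases(epi: EpidemiologySpec) -> float:
    """Prevalent case count: prevalence per 100k scaled to the population."""
    return epi.prevalence_per_100k * epi.population / 100_000.0


def diagnosed_cases(prevalent: float, diagnostic_rate: float) -> float:
    """Diagnosed case count under a given diagnostic rate."""
    if not 0.0 <= diagnostic_rate <= 1.0:
        raise DomainError(f"diagnostic_rate must be in [0,1], got {diagnostic_rate}")
    return prevalent * diagnostic_rate


def case_counts(epi: EpidemiologySpec) -> CaseCounts:
    prevalent = prevalent_cases(epi)
    return CaseCounts(
        prevalent=prevalent,
        diagnosed=diagnosed_cases(prevalent, epi.diagnostic_rate),
    )


def annualization_ratio(incidence_per_100k: float, prevalence_per_100k: float) -> float:
    """Incidence over prevalence: converts one-off diagnostic cost to EUR/year."""
    if prevalence_per_100k <= 0:
        raise DomainError(f"prevalence must be > 0, got {prevalence_per_100k}")
    if incidence_per_100k < 0:
        raise DomainError(f"incidence must be >= 0, got {incidence_per_100k}")
    return incidence_per_100k / prevalence_per_100k


def deale_annual_mortality(median_survival_months: float) -> float:
    """Annual mortality as reciprocal life expectancy, capped at 1."""
    if median_survival_months <= 0:
        raise DomainError(
            f"median survival must be > 0 months, got {median_survival_months}"
        )
    return min(12.0 / median_survival_months, 1.0)
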
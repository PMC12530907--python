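"""Occult-metastasis prevalence and population-level cost extrapolation.

Registry staging counts (8,802 clinical T1-2 oral cancers, of which 3,427
had pathological neck staging and 316 harboured cervical metastasis) give
the occult-metastasis prevalence used as the baseline transition
probability, and the denominators for scaling per-patient strategy costs to
the population level.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

__all__ = [
    "PopulationTable",
    "DEFAULT_POPULATION",
    "PopulationProjection",
    "occult_prevalence",
    "projected_reduction",
    "reduction_range",
    "extrapolate_population",
]


@dataclass(frozen=True)
class PopulationTable:
    """Registry staging counts."""

    n_total_cT12: int
    n_staged: int
    n_metastatic: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_metastatic <= self.n_staged <= self.n_total_cT12:
            raise ValueError(
                "counts must satisfy 0 <= n_metastatic <= n_staged <= n_total_cT12, "
                f"got ({self.n_total_cT12}, {self.n_staged}, {self.n_metastatic})"
            )


#: The registry series used throughout as default.
DEFAULT_POPULATION = PopulationTable(
    n_total_cT12=8802, n_staged=3427, n_metastatic=316
)


def occult_prevalence(table: PopulationTable) -> float:
    """Occult-metastasis prevalence among pathologically staged patients:
    ``n_metastatic / n_staged``."""
    if table.n_staged == 0:
        raise ValueError("prevalence undefined: no pathologically staged patients")
    return table.n_metastatic / table.n_staged


def projected_reduction(mean_slnb_strategy: float, mean_snd_strategy: float) -> float:
    """Percent cost reduction of the SLNB-first strategy relative to upfront
    SND: ``100 * (mean_snd - mean_slnb) / mean_snd``.  Negative when SLNB is
    the costlier strategy."""
    if not mean_snd_strategy > 0:
        raise ValueError(f"SND strategy mean must be > 0, got {mean_snd_strategy}")
    return 100.0 * (mean_snd_strategy - mean_slnb_strategy) / mean_snd_strategy


def reduction_range(
    mean_slnb: float, sd_slnb: float, mean_snd: float, sd_snd: float,
    k: float = 1.0,
) -> tuple[float, float]:
    """A (low, high) percent-reduction range from lower/upper per-patient
    cost bounds at ``mean +/- k*SD`` of each arm.

    This is a reconstruction of a reduction *range* from arm-level cost
    spread, pairing each arm's pessimistic bound with the other's optimistic
    bound; it is not uniquely determined by arm summaries and is labelled as
    such in outputs.
    """
    low = projected_reduction(mean_slnb + k * sd_slnb, mean_snd - k * sd_snd)
    high = projected_reduction(mean_slnb - k * sd_slnb, mean_snd + k * sd_snd)
    return low, high


_SCOPES = ("staged_only", "all_cT12")


@dataclass(frozen=True)
class PopulationProjection:
    """Population-level totals per strategy and the implied savings."""

    scope: str
    n_patients: int
    total_slnb_strategy: float
    total_snd_strategy: float
    savings_absolute: float
    savings_percent: float
    prevalence_transported: bool  # True when prevalence is assumed to extend
                                  # beyond the staged subset (all_cT12 scope)

    def to_dict(self) -> dict:
        return asdict(self)


def extrapolate_population(
    table: PopulationTable,
    mean_slnb_strategy: float,
    mean_snd_strategy: float,
    scope: str = "staged_only",
) -> PopulationProjection:
    """Scale per-patient strategy means to the population.

    ``scope='staged_only'`` multiplies by the pathologically staged count
    (where the prevalence is actually measured); ``'all_cT12'`` extends to
    every clinical T1-2 patient under the assumption that the prevalence
    transports, and flags that assumption in the output.
    """
    if scope not in _SCOPES:
        raise ValueError(f"scope must be one of {_SCOPES}, got {scope!r}")
    n = table.n_staged if scope == "staged_only" else table.n_total_cT12
    total_slnb = n * mean_slnb_strategy
    total_snd = n * mean_snd_strategy
    return PopulationProjection(
        scope=scope,
        n_patients=n,
        total_slnb_strategy=total_slnb,
        total_snd_strategy=total_snd,
        savings_absolute=total_snd - total_slnb,
        savings_percent=projected_reduction(mean_slnb_strategy, mean_snd_strategy),
        prevalence_transported=(scope == "all_cT12"),
    )
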
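"""Lifetime excess cancer risk from RPF-adjusted PAH intake.

Risk for a given BaP-equivalent shrimp concentration is the linear
slope-factor model

    Risk = [C_BaPeq (mg/kg) * IR (kg/day) * 365 (days/yr) * ED (yr)]
           / [BW (kg) * AT (days)] * OSF,

with exposure duration ED drawn uniformly on 5-10 years, averaging time AT a
78-year life span (28,470 days), and the oral slope factor OSF = 7.3 per
mg/kg/day for benzo[a]pyrene.  Consumption is assumed daily (365 days/year),
a conservative choice.

The tiered analysis re-evaluates the risk distribution as the analyte list
expands (7 cPAHs -> + unsubstituted -> + alkylated) under common random
numbers, so per-tier distributions scale exactly with the tier BaP-equivalent
totals.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .chemistry import NG_PER_G_TO_PPM, censored_bap_equivalents, bap_equivalents
from .distributions import FittedDistribution
from .exceptions import ValidationError
from .summaries import RiskDistributionSummary, summarize_distribution

__all__ = [
    "DEFAULT_ORAL_SLOPE_FACTOR",
    "DEFAULT_LIFESPAN_DAYS",
    "CancerModelConfig",
    "cancer_risk_point",
    "cancer_risk_monte_carlo",
    "tiered_risk_analysis",
]

DEFAULT_ORAL_SLOPE_FACTOR = 7.3  # (mg/kg/day)^-1, benzo[a]pyrene
DEFAULT_LIFESPAN_DAYS = 28_470.0  # 78 years x 365 days
DAYS_PER_YEAR = 365.0


def cancer_risk_point(
    bap_eq_mg_per_kg: float,
    ir_kg_per_day: float,
    bw_kg: float,
    ed_years: float,
    osf: float = DEFAULT_ORAL_SLOPE_FACTOR,
    lifespan_days: float = DEFAULT_LIFESPAN_DAYS,
    days_per_year: float = DAYS_PER_YEAR,
) -> float:
    """Deterministic lifetime excess cancer risk (dimensionless)."""
    if bw_kg <= 0:
        raise ValidationError(f"body weight must be positive, got {bw_kg}")
    if bap_eq_mg_per_kg < 0 or ir_kg_per_day < 0:
        raise ValidationError("BaP-equivalent concentration and intake must be nonnegative")
    if ed_years < 0:
        raise ValidationError("exposure duration must be nonnegative")
    if ed_years * days_per_year > lifespan_days:
        raise ValidationError(
            f"exposure duration {ed_years} yr exceeds the averaging lifespan "
            f"({lifespan_days / days_per_year:.1f} yr)"
        )
    return (
        bap_eq_mg_per_kg * ir_kg_per_day * days_per_year * ed_years
        / (bw_kg * lifespan_days)
        * osf
    )


@dataclass
class CancerModelConfig:
    """Inputs for the Monte Carlo cancer-risk simulation.

    ``ir_dist`` must be in kg shrimp/day; use :meth:`from_intake_g_per_day`
    to convert a fitted g/day intake distribution once, at construction.
    """

    bap_eq_mg_per_kg: float
    ir_dist: FittedDistribution
    bw_dist: FittedDistribution
    ed_dist: FittedDistribution = field(
        default_factory=lambda: FittedDistribution.uniform(5.0, 10.0)
    )
    oral_slope_factor: float = DEFAULT_ORAL_SLOPE_FACTOR
    lifespan_days: float = DEFAULT_LIFESPAN_DAYS
    days_per_year: float = DAYS_PER_YEAR
    n_iter: int = 10_000
    seed: int = 0

    @classmethod
    def from_intake_g_per_day(cls, bap_eq_mg_per_kg, ir_dist_g_per_day, bw_dist, **kw):
        return cls(
            bap_eq_mg_per_kg=bap_eq_mg_per_kg,
            ir_dist=ir_dist_g_per_day.scaled(1e-3),
            bw_dist=bw_dist,
            **kw,
        )

    def validate(self) -> None:
        if self.bap_eq_mg_per_kg < 0:
            raise ValidationError("bap_eq_mg_per_kg must be nonnegative")
        for name in ("oral_slope_factor", "lifespan_days", "days_per_year"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_iter < 1:
            raise ValidationError("n_iter must be >= 1")


def _draw_exposure_factors(config: CancerModelConfig):
    """Common-random-number draws of (IR, BW, ED); one child stream each."""
    n, seed = config.n_iter, config.seed
    ir = config.ir_dist.sample(n, child_rng(seed, "cancer:ir"))
    bw = config.bw_dist.sample(n, child_rng(seed, "cancer:bw"))
    ed = config.ed_dist.sample(n, child_rng(seed, "cancer:ed"))
    if np.any(bw <= 0):
        raise ValidationError(
            "body-weight draws produced nonpositive values; truncate the "
            "body-weight distribution to positive support"
        )
    return ir, bw, ed


def _risk_samples(config: CancerModelConfig) -> np.ndarray:
    ir, bw, ed = _draw_exposure_factors(config)
    return (
        config.bap_eq_mg_per_kg * ir * config.days_per_year * ed
        / (bw * config.lifespan_days)
        * config.oral_slope_factor
    )


def cancer_risk_monte_carlo(
    config: CancerModelConfig, label: Optional[str] = None
) -> RiskDistributionSummary:
    """Monte Carlo lifetime-risk distribution; deterministic given seed.

    Histogram: 50 equal-width bins from 0 to the 99.9th percentile (points
    beyond are counted in the last bin so relative frequencies sum to 1).
    """
    config.validate()
    risk = _risk_samples(config)
    return summarize_distribution(
        risk, label=label, hist_range=(0.0, float(np.percentile(risk, 99.9)))
    )


def tiered_risk_analysis(
    tiers: Sequence[str],
    meta: pd.DataFrame,
    config: CancerModelConfig,
    concentrations: Optional[pd.DataFrame] = None,
    default_rpf: float | None = 1.0,
) -> dict:
    """Risk distributions for an expanding analyte list, one per tier.

    The tier BaP-equivalent totals come from the chemistry module: the mean
    over samples of a substituted concentration table if one is supplied,
    otherwise the fully censored LOD/sqrt(2) desk value.  All tiers reuse the
    same draw sequence (common random numbers), so every percentile scales
    exactly with the tier total.  ``config.bap_eq_mg_per_kg`` is ignored.
    """
    if len(tiers) == 0:
        raise ValidationError("tiered_risk_analysis requires at least one tier")
    config.validate()
    unit_config = replace(config, bap_eq_mg_per_kg=1.0)
    risk_per_unit = _risk_samples(unit_config)  # risk per (mg BaPeq/kg)
    hist_hi = float(np.percentile(risk_per_unit, 99.9))
    out = {}
    for tier in tiers:
        if concentrations is not None:
            bapeq_ug = float(
                bap_equivalents(concentrations, meta, tier, default_rpf).mean()
            )
        else:
            bapeq_ug = censored_bap_equivalents(meta, tier, default_rpf)
        bapeq_mg = bapeq_ug * NG_PER_G_TO_PPM
        risk = bapeq_mg * risk_per_unit
        out[tier] = summarize_distribution(
            risk, label=tier, hist_range=(0.0, bapeq_mg * hist_hi)
        )
    return out
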
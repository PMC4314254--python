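"""Noncancer risk: average daily intake and hazard quotients.

Average daily intake (mg/kg body weight-day) for one PAH is

    ADI = C * IR / (BW * CF)

with C the tissue concentration in ppm (mg PAH/kg shrimp), IR the shrimp
intake rate (g/day), BW body weight (kg) and CF = 1000 g/kg.  The hazard
quotient is ADI divided by the chemical's reference dose; HQ > 1 flags a
potential noncancer concern.

Both deterministic point estimates (mean and 95th-percentile consumers) and
Monte Carlo HQ distributions (independent draws of concentration, intake and
body weight per iteration) are provided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._rng import child_rng
from .distributions import FittedDistribution
from .exceptions import ValidationError
from .summaries import RiskDistributionSummary, summarize_distribution

__all__ = [
    "CF_G_PER_KG",
    "average_daily_intake",
    "hazard_quotient",
    "HazardQuotientResult",
    "hq_point_table",
    "hq_monte_carlo",
]

logger = logging.getLogger(__name__)

#: grams of shrimp per kilogram of shrimp
CF_G_PER_KG = 1000.0


def average_daily_intake(
    conc_ppm: float, intake_g_per_day: float, body_weight_kg: float, cf: float = CF_G_PER_KG
) -> float:
    """Average daily PAH intake in mg/kg body weight-day."""
    if body_weight_kg <= 0:
        raise ValidationError(f"body weight must be positive, got {body_weight_kg}")
    if conc_ppm < 0 or intake_g_per_day < 0:
        raise ValidationError("concentration and intake rate must be nonnegative")
    return conc_ppm * intake_g_per_day / (body_weight_kg * cf)


@dataclass(frozen=True)
class HazardQuotientResult:
    analyte: str
    rfd: float
    adi: float
    hq: float
    variant: str

    @property
    def exceeds_one(self) -> bool:
        return self.hq > 1.0


def hazard_quotient(adi: float, rfd: float) -> float:
    """Hazard quotient = daily intake / reference dose."""
    if rfd <= 0:
        raise ValidationError(f"reference dose must be positive, got {rfd}")
    if adi < 0:
        raise ValidationError("average daily intake must be nonnegative")
    return adi / rfd


def hq_point_table(
    levels_ppm: Mapping[str, float],
    rfds: Mapping[str, float],
    ir_values: Mapping[str, float],
    body_weight_kg: float,
    cf: float = CF_G_PER_KG,
) -> pd.DataFrame:
    """Deterministic hazard-quotient table.

    One row per analyte; one ``hq_<variant>`` column per entry of
    ``ir_values`` (typically mean and p95 consumption).  Analytes without a
    reference dose are skipped with a warning.
    """
    rows = []
    for analyte, level in levels_ppm.items():
        rfd = rfds.get(analyte)
        if rfd is None or not np.isfinite(rfd):
            logger.warning("analyte '%s' has no reference dose; skipped", analyte)
            continue
        row = {"analyte": analyte, "rfd_mg_per_kg_day": rfd, "level_ppm": level}
        for variant, ir in ir_values.items():
            adi = average_daily_intake(level, ir, body_weight_kg, cf)
            row[f"hq_{variant}"] = hazard_quotient(adi, rfd)
        rows.append(row)
    columns = ["analyte", "rfd_mg_per_kg_day", "level_ppm"] + [
        f"hq_{v}" for v in ir_values
    ]
    return pd.DataFrame(rows, columns=columns)


def hq_monte_carlo(
    conc_dist: FittedDistribution,
    ir_dist: FittedDistribution,
    bw_dist: FittedDistribution,
    rfd: float,
    n_iter: int = 10_000,
    seed: int = 0,
    label: Optional[str] = None,
    cf: float = CF_G_PER_KG,
) -> RiskDistributionSummary:
    """Monte Carlo hazard-quotient distribution.

    Per iteration the concentration (ppm), intake rate (g/day) and body
    weight (kg) are drawn independently from their own child RNG streams,
    then the HQ is computed through the deterministic equations.
    Deterministic given seed.
    """
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    if rfd <= 0:
        raise ValidationError(f"reference dose must be positive, got {rfd}")
    conc = conc_dist.sample(n_iter, child_rng(seed, "hq:conc"))
    ir = ir_dist.sample(n_iter, child_rng(seed, "hq:ir"))
    bw = bw_dist.sample(n_iter, child_rng(seed, "hq:bw"))
    if np.any(bw <= 0):
        raise ValidationError(
            "body-weight draws produced nonpositive values; the body-weight "
            "distribution must be truncated to positive support"
        )
    hq = conc * ir / (bw * cf) / rfd
    return summarize_distribution(
        hq, label=label, hist_range=(0.0, float(np.percentile(hq, 99.9)))
    )
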
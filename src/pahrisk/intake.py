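"""Per-respondent daily shrimp intake rates from survey responses.

Intake (g shrimp/day) is the product of shrimp per meal, grams per shrimp
(from the commercial count-per-pound size class), and meals per week, divided
by 7.  Grams per shrimp come from a size-conversion table; the default uses
U.S. commercial count-per-pound class midpoints (small 51-60, medium 41-50,
large 31-40, extra-large 26-30 per lb; 1 lb = 453.592 g) and can be replaced
by any CSV with columns size_class, grams_per_shrimp.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "SizeConversionTable",
    "grams_per_shrimp",
    "intake_rate",
    "intake_table",
    "IntakeResult",
]

DAYS_PER_WEEK = 7.0


class SizeConversionTable:
    """Mapping of size-class label to grams per shrimp."""

    def __init__(self, mapping: Mapping[str, float]):
        if not mapping:
            raise ValidationError("size conversion table is empty")
        for cls, grams in mapping.items():
            if not grams > 0:
                raise ValidationError(
                    f"grams_per_shrimp for size class '{cls}' must be > 0, got {grams}"
                )
        self._map = dict(mapping)

    @classmethod
    def default(cls) -> "SizeConversionTable":
        with resources.files("pahrisk.data").joinpath("size_classes.csv").open() as fh:
            return cls.from_csv(fh)

    @classmethod
    def from_csv(cls, path_or_buf) -> "SizeConversionTable":
        df = pd.read_csv(path_or_buf)
        missing = {"size_class", "grams_per_shrimp"} - set(df.columns)
        if missing:
            raise ValidationError(f"size conversion CSV missing columns: {sorted(missing)}")
        return cls(dict(zip(df["size_class"], df["grams_per_shrimp"].astype(float))))

    def __contains__(self, size_class: str) -> bool:
        return size_class in self._map

    @property
    def classes(self) -> list:
        return sorted(self._map)

    def grams(self, size_class: str) -> float:
        try:
            return self._map[size_class]
        except KeyError:
            raise ValidationError(
                f"unknown size class '{size_class}'; available: {self.classes}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"size_class": list(self._map), "grams_per_shrimp": list(self._map.values())}
        )


def grams_per_shrimp(size_class: str, table: SizeConversionTable) -> float:
    """Grams of edible shrimp per animal for a commercial size class."""
    return table.grams(size_class)


def intake_rate(record, table: SizeConversionTable) -> float:
    """Daily shrimp intake (g/day) for one respondent.

    ``record`` is any mapping with keys shrimp_per_meal, meals_per_week and
    size_class (a pandas Series row works).
    """
    spm = float(record["shrimp_per_meal"])
    mpw = float(record["meals_per_week"])
    if spm < 0 or mpw < 0:
        raise ValidationError(
            f"shrimp_per_meal and meals_per_week must be nonnegative "
            f"(got {spm}, {mpw})"
        )
    grams = grams_per_shrimp(record["size_class"], table)
    return spm * grams * mpw / DAYS_PER_WEEK


@dataclass(frozen=True)
class IntakeResult:
    """Per-respondent intake rates plus their summary statistics."""

    rates: pd.DataFrame  # respondent_id, intake_g_per_day
    mean: float
    sd: float
    p95: float

    @property
    def n(self) -> int:
        return len(self.rates)


def intake_table(records: pd.DataFrame, table: SizeConversionTable) -> IntakeResult:
    """Intake rates for a whole survey table.

    The summary mean is the arithmetic mean of per-respondent rates, the SD is
    the population SD (a single respondent has SD 0), and the 95th percentile
    uses linear interpolation on order statistics.
    """
    if len(records) == 0:
        raise ValidationError("intake_table requires at least one survey record")
    spm = records["shrimp_per_meal"].astype(float).to_numpy()
    mpw = records["meals_per_week"].astype(float).to_numpy()
    if np.any(spm < 0) or np.any(mpw < 0):
        raise ValidationError("negative shrimp_per_meal or meals_per_week in survey table")
    grams = records["size_class"].map(lambda c: table.grams(c)).to_numpy(dtype=float)
    rates = spm * grams * mpw / DAYS_PER_WEEK
    out = pd.DataFrame(
        {"respondent_id": records["respondent_id"].to_numpy(), "intake_g_per_day": rates}
    )
    return IntakeResult(
        rates=out,
        mean=float(np.mean(rates)),
        sd=float(np.std(rates)),
        p95=float(np.percentile(rates, 95)),
    )
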
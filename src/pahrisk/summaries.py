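"""Summaries of Monte Carlo output distributions.

Percentiles use linear interpolation on order statistics throughout the
package (the same estimator numpy's default percentile uses), and histograms
are relative-frequency histograms: counts divided by the total number of
points, so bar heights sum to 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["RiskDistributionSummary", "summarize_distribution"]


@dataclass(frozen=True)
class RiskDistributionSummary:
    """Mean, SD, percentiles, and relative-frequency histogram of one Monte
    Carlo output (hazard quotient or cancer risk)."""

    mean: float
    sd: float
    p5: float
    p50: float
    p95: float
    p99: float
    histogram_edges: np.ndarray
    histogram_freq: np.ndarray
    n: int
    label: Optional[str] = None

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.histogram_edges[:-1],
                "bin_right": self.histogram_edges[1:],
                "rel_freq": self.histogram_freq,
            }
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "p5": self.p5,
            "p50": self.p50,
            "p95": self.p95,
            "p99": self.p99,
        }


def summarize_distribution(
    samples, bins: int = 50, label: Optional[str] = None, hist_range=None
) -> RiskDistributionSummary:
    """Summarise a sample vector.

    ``hist_range`` defaults to (min, max); risk engines pass (0, p99.9) to get
    the conventional truncated display range.  Relative frequencies always sum
    to 1: points falling beyond the histogram range are counted in the outer
    bins.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValidationError("cannot summarise an empty sample")
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples contain non-finite values")
    p5, p50, p95, p99 = np.percentile(x, [5, 50, 95, 99])
    if hist_range is not None:
        lo, hi = hist_range
        if not hi > lo:
            hist_range = None
    if hist_range is None:
        counts, edges = np.histogram(x, bins=bins)
    else:
        clipped = np.clip(x, lo, hi)
        counts, edges = np.histogram(clipped, bins=bins, range=(lo, hi))
    # extended-precision accumulation so degenerate (constant) inputs
    # summarise to the point value exactly
    mean = float(np.mean(x, dtype=np.longdouble))
    sd = float(np.sqrt(np.mean((x.astype(np.longdouble) - mean) ** 2)))
    return RiskDistributionSummary(
        mean=mean,
        sd=sd,
        p5=float(p5),
        p50=float(p50),
        p95=float(p95),
        p99=float(p99),
        histogram_edges=edges,
        histogram_freq=counts / x.size,
        n=int(x.size),
        label=label,
    )
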
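"""Parametric distribution fitting, BIC ranking, and (truncated) sampling.

Candidate families follow the exposure-assessment convention: body weight is
modelled with normal / log-normal / Pearson type V, intake rate with Weibull /
log-normal / Pearson type VI.  Pearson V is identified with the inverse-gamma
family and Pearson VI with the (scaled) beta-prime family, the standard
identifications.  Fits are maximum likelihood with method-of-moments starting
values, ranked by the Bayesian information criterion

    BIC = k ln(n) - 2 ln(L-hat),

smaller is better.  A ``constant`` (point-mass) pseudo-family is provided so
Monte Carlo inputs can be degenerated for oracle checks.

Truncated sampling uses the inverse-CDF on the restricted quantile range, so
draws target the renormalised (truncated) density exactly.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gamma as gamma_fn

from ._rng import as_rng
from .exceptions import FitError, ValidationError

__all__ = [
    "FittedDistribution",
    "FailedFit",
    "fit_mle",
    "rank_fits",
    "sample",
    "FAMILIES",
    "BODY_WEIGHT_FAMILIES",
    "INTAKE_FAMILIES",
]

# family -> (number of free parameters, requires strictly positive support)
FAMILIES = {
    "normal": (2, False),
    "lognormal": (2, True),
    "pearson5": (2, True),
    "weibull": (2, True),
    "pearson6": (3, True),
    "uniform": (2, False),
    "constant": (1, False),
}

BODY_WEIGHT_FAMILIES = ("normal", "lognormal", "pearson5")
INTAKE_FAMILIES = ("weibull", "lognormal", "pearson6")


def _frozen(family: str, params: tuple):
    if family == "normal":
        mu, sigma = params
        return stats.norm(loc=mu, scale=sigma)
    if family == "lognormal":
        mu, sigma = params  # parameters of log(X)
        return stats.lognorm(s=sigma, scale=math.exp(mu))
    if family == "pearson5":
        shape, scale = params
        return stats.invgamma(shape, scale=scale)
    if family == "weibull":
        shape, scale = params
        return stats.weibull_min(shape, scale=scale)
    if family == "pearson6":
        a, b, scale = params
        return stats.betaprime(a, b, scale=scale)
    if family == "uniform":
        lower, upper = params
        return stats.uniform(loc=lower, scale=upper - lower)
    raise ValidationError(f"unknown family '{family}'")


@dataclass(frozen=True)
class FittedDistribution:
    """A parametric family with estimated parameters, fit statistics, and
    optional truncation bounds; samplable."""

    family: str
    params: tuple
    log_likelihood: float = math.nan
    bic: float = math.nan
    n: int = 0
    truncation: Optional[tuple] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown family '{self.family}'; known: {sorted(FAMILIES)}"
            )
        if self.truncation is not None:
            lower, upper = self.truncation
            if not lower < upper:
                raise ValidationError(
                    f"truncation lower bound {lower} must be < upper bound {upper}"
                )

    # -- distribution surface ------------------------------------------------
    def frozen(self):
        """The untruncated scipy frozen distribution (not defined for constant)."""
        return _frozen(self.family, self.params)

    def cdf(self, x):
        if self.family == "constant":
            (c,) = self.params
            return np.where(np.asarray(x, dtype=float) >= c, 1.0, 0.0)
        return self.frozen().cdf(x)

    def ppf(self, q):
        if self.family == "constant":
            (c,) = self.params
            return np.full_like(np.asarray(q, dtype=float), c)
        return self.frozen().ppf(q)

    def logpdf(self, x):
        if self.family == "constant":
            raise ValidationError("point mass has no density")
        return self.frozen().logpdf(x)

    def mean(self) -> float:
        if self.family == "constant":
            return float(self.params[0])
        m = self.frozen().mean()
        if self.truncation is None:
            return float(m)
        # truncated mean via numerical quadrature on the quantile scale
        lo, hi = self.truncation
        f = self.frozen()
        qlo, qhi = f.cdf(lo), f.cdf(hi)
        qs = np.linspace(qlo, qhi, 20001)[1:-1]
        return float(np.mean(f.ppf(qs)))

    def truncated_cdf(self, x):
        """CDF of the truncated distribution (identity when untruncated)."""
        if self.truncation is None:
            return self.cdf(x)
        lo, hi = self.truncation
        f = self.frozen()
        qlo, qhi = f.cdf(lo), f.cdf(hi)
        return np.clip((f.cdf(x) - qlo) / (qhi - qlo), 0.0, 1.0)

    # -- sampling ------------------------------------------------------------
    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw ``n`` values; inverse-CDF on the restricted quantile range when
        truncated, so every draw lies strictly inside the bounds."""
        if n < 0:
            raise ValidationError("n must be nonnegative")
        rng = as_rng(seed)
        if self.family == "constant":
            return np.full(n, float(self.params[0]))
        f = self.frozen()
        if self.truncation is None:
            u = rng.uniform(0.0, 1.0, n)
            return np.asarray(f.ppf(u), dtype=float)
        lo, hi = self.truncation
        qlo, qhi = f.cdf(lo), f.cdf(hi)
        if qhi - qlo < 1e-12:
            raise ValidationError(
                f"truncation interval ({lo}, {hi}) carries ~zero probability mass "
                f"under {self.family}{self.params}"
            )
        u = rng.uniform(qlo, qhi, n)
        x = np.asarray(f.ppf(u), dtype=float)
        # guard against boundary hits from floating point round-trips
        return np.clip(x, np.nextafter(lo, np.inf), np.nextafter(hi, -np.inf))

    # -- transforms ----------------------------------------------------------
    def scaled(self, factor: float) -> "FittedDistribution":
        """The distribution of ``factor * X`` (e.g. g/day -> kg/day).

        Fit statistics do not survive a change of variable and are dropped.
        """
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        p = self.params
        if self.family == "normal":
            newp = (p[0] * factor, p[1] * factor)
        elif self.family == "lognormal":
            newp = (p[0] + math.log(factor), p[1])
        elif self.family in ("pearson5", "weibull"):
            newp = (p[0], p[1] * factor)
        elif self.family == "pearson6":
            newp = (p[0], p[1], p[2] * factor)
        elif self.family == "uniform":
            newp = (p[0] * factor, p[1] * factor)
        elif self.family == "constant":
            newp = (p[0] * factor,)
        trunc = None
        if self.truncation is not None:
            trunc = (self.truncation[0] * factor, self.truncation[1] * factor)
        return FittedDistribution(self.family, newp, truncation=trunc)

    def truncated(self, lower: float, upper: float) -> "FittedDistribution":
        return replace(self, truncation=(float(lower), float(upper)))

    # -- serialisation -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "params": list(self.params),
            "log_likelihood": None
            if math.isnan(self.log_likelihood)
            else self.log_likelihood,
            "bic": None if math.isnan(self.bic) else self.bic,
            "n": self.n,
            "truncation": None if self.truncation is None else list(self.truncation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedDistribution":
        return cls(
            family=d["family"],
            params=tuple(d["params"]),
            log_likelihood=math.nan
            if d.get("log_likelihood") is None
            else d["log_likelihood"],
            bic=math.nan if d.get("bic") is None else d["bic"],
            n=d.get("n", 0),
            truncation=None if d.get("truncation") is None else tuple(d["truncation"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FittedDistribution":
        return cls.from_dict(json.loads(s))

    # -- constructors for hand-specified inputs ------------------------------
    @classmethod
    def normal(cls, mean, sd, truncation=None):
        if sd <= 0:
            raise ValidationError("sd must be positive")
        return cls("normal", (float(mean), float(sd)), truncation=truncation)

    @classmethod
    def lognormal(cls, mu, sigma, truncation=None):
        if sigma <= 0:
            raise ValidationError("sigma must be positive")
        return cls("lognormal", (float(mu), float(sigma)), truncation=truncation)

    @classmethod
    def uniform(cls, lower, upper):
        if not lower < upper:
            raise ValidationError("uniform requires lower < upper")
        return cls("uniform", (float(lower), float(upper)))

    @classmethod
    def constant(cls, value):
        return cls("constant", (float(value),))


@dataclass(frozen=True)
class FailedFit:
    """Placeholder for a family that failed to fit; always ranks last."""

    family: str
    error: str
    bic: float = math.inf
    log_likelihood: float = -math.inf


def _validate_samples(x: np.ndarray, family: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValidationError(f"need at least 2 samples to fit, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("samples contain non-finite values")
    _, positive = FAMILIES[family]
    if positive and np.any(x <= 0):
        raise ValidationError(
            f"family '{family}' has positive support but samples contain "
            f"nonpositive values (min {x.min()})"
        )
    if np.ptp(x) == 0 and family != "constant":
        raise FitError(
            f"degenerate sample (all values equal {x[0]}); "
            f"cannot fit family '{family}'"
        )
    return x


def _mle_params(x: np.ndarray, family: str) -> tuple:
    """Maximum-likelihood parameter estimates with deterministic
    method-of-moments starting values."""
    m, s = float(np.mean(x)), float(np.std(x))  # MLE variance (ddof=0)
    if family == "normal":
        return (m, s)
    if family == "lognormal":
        logs = np.log(x)
        return (float(np.mean(logs)), float(np.std(logs)))
    if family == "uniform":
        return (float(np.min(x)), float(np.max(x)))
    if family == "constant":
        return (m,)
    if family == "pearson5":
        v = s**2
        a0 = m * m / v + 2.0 if v > 0 else 3.0
        scale0 = m * (a0 - 1.0)
        a, loc, scale_ = stats.invgamma.fit(x, a0, floc=0, scale=scale0)
        return (float(a), float(scale_))
    if family == "weibull":
        cv = s / m
        c0 = cv ** (-1.086) if cv > 0 else 1.0  # classic moment approximation
        scale0 = m / gamma_fn(1.0 + 1.0 / c0)
        c, loc, scale_ = stats.weibull_min.fit(x, c0, floc=0, scale=scale0)
        return (float(c), float(scale_))
    if family == "pearson6":
        # fixed start (alpha, beta, scale) = (4, 5, mean): with beta-1 = 4 the
        # implied mean matches the sample mean; deterministic by construction
        a, b, loc, scale_ = stats.betaprime.fit(x, 4.0, 5.0, floc=0, scale=m)
        return (float(a), float(b), float(scale_))
    raise ValidationError(f"unknown family '{family}'")


def fit_mle(samples, family: str) -> FittedDistribution:
    """Fit ``family`` to ``samples`` by maximum likelihood.

    Returns a :class:`FittedDistribution` whose log-likelihood is the sum of
    log-densities at the estimate and whose BIC is ``k ln n - 2 logL``.
    Deterministic: starting values are method-of-moments functions of the data.
    """
    if family == "constant":
        raise ValidationError("the constant pseudo-family is not a fitting candidate")
    x = _validate_samples(samples, family)
    try:
        params = _mle_params(x, family)
    except (FitError, ValidationError):
        raise
    except Exception as exc:  # optimizer failures from scipy
        raise FitError(f"MLE for family '{family}' failed: {exc!r}") from exc
    if not all(np.isfinite(params)):
        raise FitError(f"MLE for family '{family}' returned non-finite parameters {params}")
    k, _ = FAMILIES[family]
    dist = _frozen(family, params)
    loglik = float(np.sum(dist.logpdf(x)))
    if not np.isfinite(loglik):
        raise FitError(
            f"log-likelihood non-finite at the '{family}' estimate {params}; "
            "fit did not converge to an interior optimum"
        )
    bic = k * math.log(x.size) - 2.0 * loglik
    return FittedDistribution(family, params, loglik, bic, int(x.size))


def rank_fits(samples, families: Sequence[str]) -> list:
    """Fit every family and rank ascending by BIC.

    Ties break by higher log-likelihood, then family name.  Families that fail
    to fit are appended last as :class:`FailedFit` records.
    """
    if len(families) < 2:
        raise ValidationError("rank_fits requires at least 2 families")
    fitted, failed = [], []
    for fam in families:
        try:
            fitted.append(fit_mle(samples, fam))
        except (FitError, ValidationError) as exc:
            failed.append(FailedFit(fam, str(exc)))
    fitted.sort(key=lambda d: (d.bic, -d.log_likelihood, d.family))
    return fitted + failed


def sample(dist: FittedDistribution, n: int, seed=None) -> np.ndarray:
    """Functional alias for :meth:`FittedDistribution.sample`."""
    return dist.sample(n, seed)
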
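"""Model/results interface tying the pipeline stages together.

`DietaryPAHRiskModel` holds the data (survey table, concentration table,
analyte metadata, size-conversion table); `fit()` derives per-respondent
intake rates, fits and BIC-ranks the candidate parametric families for body
weight and intake, substitutes nondetects and aggregates concentrations, and
returns a `DietaryPAHRiskResults` carrying the estimates.  Hazard-quotient
and cancer-risk computation — deterministic and Monte Carlo — and plotting
hang off the results object.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import chemistry, noncancer
from .cancer import (
    CancerModelConfig,
    cancer_risk_monte_carlo,
    cancer_risk_point,
    tiered_risk_analysis,
)
from .chemistry import NG_PER_G_TO_PPM
from .distributions import (
    BODY_WEIGHT_FAMILIES,
    INTAKE_FAMILIES,
    FailedFit,
    FittedDistribution,
    rank_fits,
)
from .exceptions import ValidationError
from .intake import IntakeResult, SizeConversionTable, intake_table
from .summaries import RiskDistributionSummary

__all__ = ["DietaryPAHRiskModel", "DietaryPAHRiskResults"]

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = [
    "respondent_id",
    "sex",
    "body_weight_kg",
    "shrimp_per_meal",
    "meals_per_week",
    "size_class",
]


class DietaryPAHRiskModel:
    """Dietary PAH exposure and risk model for a surveyed population.

    Parameters
    ----------
    survey : DataFrame
        One row per respondent (columns: respondent_id, sex, body_weight_kg,
        shrimp_per_meal, meals_per_week, size_class).
    concentrations : DataFrame
        Per composite sample x analyte measurements (columns: sample_id,
        analyte, value_ng_per_g, nondetect, lod_ng_per_g).
    meta : DataFrame, optional
        Analyte metadata; the packaged table by default.
    size_table : SizeConversionTable, optional
        Size-class to grams-per-shrimp conversion; packaged default.
    """

    def __init__(self, survey, concentrations, meta=None, size_table=None):
        missing = set(SURVEY_COLUMNS) - set(survey.columns)
        if missing:
            raise ValidationError(f"survey table missing columns: {sorted(missing)}")
        if not (survey["body_weight_kg"] > 0).all():
            raise ValidationError("survey body weights must be strictly positive")
        self.survey = survey.reset_index(drop=True)
        self.concentrations = concentrations.reset_index(drop=True)
        self.meta = chemistry.load_analyte_metadata() if meta is None else meta
        self.size_table = size_table if size_table is not None else SizeConversionTable.default()

    @classmethod
    def from_csv(cls, survey_csv, chemistry_csv, meta_csv=None, size_csv=None):
        survey = pd.read_csv(survey_csv)
        conc = pd.read_csv(chemistry_csv)
        meta = chemistry.load_analyte_metadata(meta_csv) if meta_csv else None
        size = SizeConversionTable.from_csv(size_csv) if size_csv else None
        return cls(survey, conc, meta=meta, size_table=size)

    @classmethod
    def from_synthetic(cls, seed: int = 0, n_respondents: int = 115, n_samples: int = 24):
        """Build the model on synthetic survey + chemistry tables emulating
        the study conditions."""
        from .synthetic import (
            ChemGenConfig,
            SurveyGenConfig,
            default_chem_config,
            generate_chemistry,
            generate_survey,
        )

        survey = generate_survey(SurveyGenConfig(n_respondents=n_respondents, seed=seed))
        meta = chemistry.load_analyte_metadata()
        conc = generate_chemistry(default_chem_config(seed=seed, n_samples=n_samples), meta)
        return cls(survey, conc, meta=meta)

    def fit(
        self,
        bw_families: Sequence[str] = BODY_WEIGHT_FAMILIES,
        ir_families: Sequence[str] = INTAKE_FAMILIES,
        bw_truncation=(0.0, 250.0),
    ) -> "DietaryPAHRiskResults":
        """Fit the exposure-factor distributions and aggregate the chemistry.

        Body weight is fitted over ``bw_families`` and the winner is truncated
        to ``bw_truncation`` for sampling; intake rate over ``ir_families``.
        Zero intake rates (non-consumers) are retained in the empirical
        summary but excluded from positive-support fitting.
        """
        intake = intake_table(self.survey, self.size_table)
        logger.info("intake rates computed for %d respondents", intake.n)

        bw = self.survey["body_weight_kg"].to_numpy(dtype=float)
        bw_fits = rank_fits(bw, bw_families)
        bw_best = _first_success(bw_fits, "body weight")
        if bw_truncation is not None:
            bw_best = bw_best.truncated(*bw_truncation)

        rates = intake.rates["intake_g_per_day"].to_numpy(dtype=float)
        positive = rates[rates > 0]
        n_zero = rates.size - positive.size
        if n_zero:
            logger.info("%d zero-consumption respondents excluded from IR fitting", n_zero)
        ir_fits = rank_fits(positive, ir_families)
        ir_best = _first_success(ir_fits, "intake rate")

        substituted = chemistry.substitute_nondetects(self.concentrations)
        n_nd = int(self.concentrations["nondetect"].astype(bool).sum())
        logger.info("substituted %d nondetects at LOD/sqrt(2)", n_nd)
        group_totals = chemistry.parent_totals(substituted, self.meta)

        return DietaryPAHRiskResults(
            model=self,
            intake=intake,
            bw_fits=bw_fits,
            ir_fits=ir_fits,
            bw_dist=bw_best,
            ir_dist=ir_best,
            substituted=substituted,
            group_totals=group_totals,
        )


def _first_success(ranked, what):
    for entry in ranked:
        if not isinstance(entry, FailedFit):
            return entry
    raise ValidationError(f"no candidate family could be fitted for {what}")


@dataclass
class DietaryPAHRiskResults:
    """Estimates from :meth:`DietaryPAHRiskModel.fit`.

    Attributes
    ----------
    intake : IntakeResult
        Per-respondent intake rates and summary (mean, SD, p95), g/day.
    bw_fits, ir_fits : list
        BIC-ranked candidate fits (failures last).
    bw_dist, ir_dist : FittedDistribution
        The selected (lowest-BIC) distributions; body weight truncated.
    substituted : DataFrame
        Concentration table after LOD/sqrt(2) substitution.
    group_totals : DataFrame
        Per-sample totals per pooled reference-dose group (homologs added to
        their parent).
    """

    model: DietaryPAHRiskModel
    intake: IntakeResult
    bw_fits: list
    ir_fits: list
    bw_dist: FittedDistribution
    ir_dist: FittedDistribution
    substituted: pd.DataFrame
    group_totals: pd.DataFrame

    # -- chemistry-derived quantities ---------------------------------------
    def mean_levels_ppm(self) -> dict:
        """Across-sample mean total concentration per reference-dose group, ppm."""
        means = self.group_totals.groupby("rfd_group")["total_ng_per_g"].mean()
        return {g: float(v) * NG_PER_G_TO_PPM for g, v in means.items()}

    def group_rfds(self) -> dict:
        return (
            self.group_totals.groupby("rfd_group")["rfd_mg_per_kg_day"]
            .first()
            .astype(float)
            .to_dict()
        )

    def tier_bap_equivalents(self, censored: bool = True, default_rpf=1.0) -> dict:
        """BaP-equivalent totals (ug/kg) per analyte tier."""
        out = {}
        for tier in chemistry.TIERS:
            if censored:
                out[tier] = chemistry.censored_bap_equivalents(
                    self.model.meta, tier, default_rpf if tier != "cpah7" else None
                )
            else:
                out[tier] = float(
                    chemistry.bap_equivalents(
                        self.substituted,
                        self.model.meta,
                        tier,
                        default_rpf if tier != "cpah7" else None,
                    ).mean()
                )
        return out

    # -- noncancer ----------------------------------------------------------
    def hazard_quotients(self, body_weight_kg: Optional[float] = None) -> pd.DataFrame:
        """Deterministic HQ table at mean and 95th-percentile consumption."""
        bw = body_weight_kg if body_weight_kg is not None else float(
            np.mean(self.model.survey["body_weight_kg"])
        )
        return noncancer.hq_point_table(
            self.mean_levels_ppm(),
            self.group_rfds(),
            {"mean": self.intake.mean, "p95": self.intake.p95},
            bw,
        )

    def hq_monte_carlo(
        self, group: str, n_iter: int = 10_000, seed: int = 0
    ) -> RiskDistributionSummary:
        """Monte Carlo HQ distribution for one pooled reference-dose group.

        The group's across-sample concentration (ppm) is modelled log-normally
        from the substituted per-sample totals.
        """
        totals = self.group_totals.loc[
            self.group_totals["rfd_group"] == group, "total_ng_per_g"
        ].to_numpy(dtype=float)
        if totals.size == 0:
            raise ValidationError(f"no concentration data for group '{group}'")
        rfd = self.group_rfds()[group]
        logs = np.log(totals * NG_PER_G_TO_PPM)
        sigma = float(np.std(logs))
        if sigma > 0:
            conc_dist = FittedDistribution.lognormal(float(np.mean(logs)), sigma)
        else:
            conc_dist = FittedDistribution.constant(float(np.exp(np.mean(logs))))
        return noncancer.hq_monte_carlo(
            conc_dist, self.ir_dist, self.bw_dist, rfd,
            n_iter=n_iter, seed=seed, label=group,
        )

    # -- cancer -------------------------------------------------------------
    def cancer_config(
        self, tier: str = "cpah7", n_iter: int = 10_000, seed: int = 0, default_rpf=1.0
    ) -> CancerModelConfig:
        bapeq_ug = self.tier_bap_equivalents(default_rpf=default_rpf)[tier]
        return CancerModelConfig.from_intake_g_per_day(
            bap_eq_mg_per_kg=bapeq_ug * NG_PER_G_TO_PPM,
            ir_dist_g_per_day=self.ir_dist,
            bw_dist=self.bw_dist,
            n_iter=n_iter,
            seed=seed,
        )

    def cancer_risk_point(self, tier: str = "cpah7", ed_years: float = 5.0) -> float:
        """Deterministic lifetime risk at mean intake, mean body weight."""
        bapeq_mg = self.tier_bap_equivalents()[tier] * NG_PER_G_TO_PPM
        bw = float(np.mean(self.model.survey["body_weight_kg"]))
        return cancer_risk_point(bapeq_mg, self.intake.mean * 1e-3, bw, ed_years)

    def cancer_risk(
        self, tier: str = "cpah7", n_iter: int = 10_000, seed: int = 0
    ) -> RiskDistributionSummary:
        return cancer_risk_monte_carlo(
            self.cancer_config(tier, n_iter, seed), label=tier
        )

    def tiered_cancer_risk(
        self,
        tiers: Sequence[str] = chemistry.TIERS,
        n_iter: int = 10_000,
        seed: int = 0,
        default_rpf: float = 1.0,
    ) -> dict:
        config = self.cancer_config(tiers[0], n_iter, seed, default_rpf)
        return tiered_risk_analysis(tiers, self.model.meta, config, default_rpf=default_rpf)

    # -- presentation --------------------------------------------------------
    def summary(self, n_iter: int = 10_000, seed: int = 0) -> str:
        """Plain-text summary of the fitted exposure model and risk estimates."""
        lines = []
        w = lines.append
        w("Dietary PAH risk assessment")
        w("=" * 64)
        w(f"Respondents: {self.intake.n}    composite samples: "
          f"{self.substituted['sample_id'].nunique()}")
        bw_mean = float(np.mean(self.model.survey['body_weight_kg']))
        w(f"Mean body weight: {bw_mean:.1f} kg")
        w(f"Mean intake rate: {self.intake.mean:.1f} g/day "
          f"(p95 {self.intake.p95:.1f} g/day)")
        w("")
        w("Fitted exposure-factor distributions (BIC-ranked, best first)")
        w("-" * 64)
        for name, fits in (("body weight [kg]", self.bw_fits), ("intake rate [g/day]", self.ir_fits)):
            w(f"{name}:")
            for f in fits:
                if isinstance(f, FailedFit):
                    w(f"    {f.family:<10} FAILED: {f.error}")
                else:
                    pars = ", ".join(f"{p:.4g}" for p in f.params)
                    w(f"    {f.family:<10} params=({pars})  logL={f.log_likelihood:.2f}  BIC={f.bic:.2f}")
        w("")
        w("Hazard quotients (deterministic; HQ > 1 flags concern)")
        w("-" * 64)
        hq = self.hazard_quotients()
        for _, r in hq.iterrows():
            w(f"    {r['analyte']:<26} RfD={r['rfd_mg_per_kg_day']:<6g} "
              f"HQ(mean)={r['hq_mean']:.2g}  HQ(p95)={r['hq_p95']:.2g}")
        w("")
        w("Lifetime excess cancer risk by analyte tier "
          f"(Monte Carlo, {n_iter} iterations)")
        w("-" * 64)
        tiered = self.tiered_cancer_risk(n_iter=n_iter, seed=seed)
        for tier, s in tiered.items():
            w(f"    {tier:<20} mean={s.mean:.2g}  p95={s.p95:.2g}  p99={s.p99:.2g}")
        return "\n".join(lines)

    def plot_risk_histogram(self, summary: RiskDistributionSummary, ax=None):
        """Relative-frequency histogram of a Monte Carlo risk distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        edges, freq = summary.histogram_edges, summary.histogram_freq
        ax.bar(edges[:-1], freq, width=np.diff(edges), align="edge", edgecolor="none")
        ax.set_xlabel(f"{summary.label or 'risk'}")
        ax.set_ylabel("relative frequency")
        return ax
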
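"""End-to-end assessment runs with machine-readable outputs and a manifest.

`run_assessment` executes the stages (synthetic generation if requested,
intake, distribution fitting, chemistry aggregation, noncancer and cancer
risk) and writes:

- ``survey.csv`` / ``chemistry.csv`` (when generated synthetically)
- ``intake.csv`` (respondent_id, intake_g_per_day)
- ``distribution_fits.json`` (ranked fits for body weight and intake)
- ``table_noncancer.csv`` (analyte, rfd, level_ppm, hq_mean, hq_p95)
- ``table_cancer.csv`` (tier, bap_eq_ug_per_kg, mean, p95, p99)
- ``histogram_<tier>.csv`` (bin_left, bin_right, rel_freq)
- ``manifest.json`` (seed, iterations, config echo, stage record counts)

Floating output is written at full precision; display rounding belongs to the
human-readable summary only.  The manifest carries no timestamp, so re-running
the same configuration yields byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .chemistry import TIERS
from .distributions import FailedFit
from .exceptions import ConfigurationError, PipelineError, ValidationError
from .model import DietaryPAHRiskModel
from .summaries import RiskDistributionSummary, summarize_distribution

__all__ = ["RunConfig", "run_assessment", "summarize_distribution"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one assessment run.

    Exactly one source per input kind: a CSV path, or synthetic generation
    (the default when no path is given).
    """

    out_dir: str = "pahrisk_out"
    seed: int = 0
    n_iter: int = 10_000
    n_respondents: int = 115
    n_samples: int = 24
    tiers: Sequence[str] = TIERS
    survey_csv: Optional[str] = None
    chemistry_csv: Optional[str] = None
    meta_csv: Optional[str] = None
    size_csv: Optional[str] = None
    default_rpf: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")
        bad = set(self.tiers) - set(TIERS)
        if bad:
            raise ConfigurationError(f"unknown tiers: {sorted(bad)}")
        for attr in ("survey_csv", "chemistry_csv", "meta_csv", "size_csv"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{attr} points to a missing file: {p}")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["tiers"] = list(self.tiers)
        return d


def _write_csv(df, path: Path, written: list) -> None:
    df.to_csv(path, index=False)
    written.append(path)


def run_assessment(config: RunConfig) -> dict:
    """Run the full pipeline; returns a dict of output paths and key results.

    On any stage failure the partial outputs written so far are removed and a
    :class:`PipelineError` naming the stage is raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list = []
    stage = "setup"
    counts = {}
    try:
        stage = "inputs"
        if config.survey_csv is None or config.chemistry_csv is None:
            from .synthetic import SurveyGenConfig, default_chem_config, generate_chemistry, generate_survey
            from .chemistry import load_analyte_metadata

            meta = load_analyte_metadata(config.meta_csv)
            survey = (
                generate_survey(
                    SurveyGenConfig(n_respondents=config.n_respondents, seed=config.seed)
                )
                if config.survey_csv is None
                else None
            )
            conc = (
                generate_chemistry(
                    default_chem_config(seed=config.seed, n_samples=config.n_samples), meta
                )
                if config.chemistry_csv is None
                else None
            )
            if survey is not None:
                _write_csv(survey, out / "survey.csv", written)
            if conc is not None:
                _write_csv(conc, out / "chemistry.csv", written)
            model = DietaryPAHRiskModel(
                survey if survey is not None else pd.read_csv(config.survey_csv),
                conc if conc is not None else pd.read_csv(config.chemistry_csv),
                meta=meta,
            )
        else:
            model = DietaryPAHRiskModel.from_csv(
                config.survey_csv, config.chemistry_csv, config.meta_csv, config.size_csv
            )
        counts["respondents"] = len(model.survey)
        counts["concentration_records"] = len(model.concentrations)
        counts["nondetects"] = int(model.concentrations["nondetect"].astype(bool).sum())

        stage = "fit"
        results = model.fit()
        _write_csv(results.intake.rates, out / "intake.csv", written)
        fits_path = out / "distribution_fits.json"
        fits_payload = {
            "body_weight": [_fit_dict(f) for f in results.bw_fits],
            "intake_rate": [_fit_dict(f) for f in results.ir_fits],
            "selected": {
                "body_weight": results.bw_dist.to_dict(),
                "intake_rate": results.ir_dist.to_dict(),
            },
        }
        fits_path.write_text(json.dumps(fits_payload, indent=2))
        written.append(fits_path)

        stage = "noncancer"
        hq = results.hazard_quotients()
        _write_csv(hq, out / "table_noncancer.csv", written)
        counts["noncancer_analytes"] = len(hq)

        stage = "cancer"
        tiered = results.tiered_cancer_risk(
            tiers=config.tiers, n_iter=config.n_iter, seed=config.seed,
            default_rpf=config.default_rpf,
        )
        bapeq = results.tier_bap_equivalents(default_rpf=config.default_rpf)
        table2 = pd.DataFrame(
            [
                {
                    "tier": tier,
                    "bap_eq_ug_per_kg": bapeq[tier],
                    "mean": s.mean,
                    "p95": s.p95,
                    "p99": s.p99,
                }
                for tier, s in tiered.items()
            ]
        )
        _write_csv(table2, out / "table_cancer.csv", written)
        for tier, s in tiered.items():
            _write_csv(s.histogram_frame(), out / f"histogram_{tier}.csv", written)
        counts["mc_iterations"] = config.n_iter

        stage = "manifest"
        manifest = {
            "package": "pahrisk",
            "version": _pkg_version,
            "seed": config.seed,
            "n_iter": config.n_iter,
            "config": config.echo(),
            "stage_counts": counts,
            "outputs": [p.name for p in written],
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        written.append(manifest_path)
    except Exception as exc:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    logger.info("run complete: %s", counts)
    return {"paths": [str(p) for p in written], "counts": counts, "results": results}


def _fit_dict(f):
    if isinstance(f, FailedFit):
        return {"family": f.family, "error": f.error}
    return f.to_dict()
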
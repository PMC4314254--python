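"""Lifetime cancer risk: the slope-factor equation, Monte Carlo simulation,
and the tiered analyte-expansion analysis."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pahrisk import (
    CancerModelConfig,
    FittedDistribution,
    ValidationError,
    cancer_risk_monte_carlo,
    cancer_risk_point,
    censored_bap_equivalents,
    tiered_risk_analysis,
)
from pahrisk.chemistry import NG_PER_G_TO_PPM


def _point(bap=6.68e-4, ir=0.0452, bw=63.0, ed=5.0, **kw):
    return cancer_risk_point(bap, ir, bw, ed, **kw)


class TestCancerRiskPoint:
    def test_seven_cpah_anchor_arithmetic(self):
        expected = 6.68e-4 * 0.0452 * 365 * 5 / (63 * 28470) * 7.3
        assert _point() == pytest.approx(expected, rel=1e-12)
        assert _point() == pytest.approx(2.24e-7, rel=1e-2)

    def test_zero_bap_eq_gives_zero_risk(self):
        assert _point(bap=0.0) == 0.0

    def test_doubling_exposure_duration_doubles_risk(self):
        assert _point(ed=10.0) == pytest.approx(2 * _point(ed=5.0), rel=1e-12)

    def test_exposure_duration_beyond_lifespan_rejected(self):
        with pytest.raises(ValidationError, match="lifespan"):
            _point(ed=100.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        bap=st.floats(1e-6, 1e-1),
        ir=st.floats(1e-3, 0.5),
        bw=st.floats(30, 200),
        ed=st.floats(0.5, 30),
        factor=st.floats(1.1, 5.0),
    )
    def test_exact_proportionality_in_each_factor(self, bap, ir, bw, ed, factor):
        base = _point(bap=bap, ir=ir, bw=bw, ed=ed)
        assert _point(bap=bap * factor, ir=ir, bw=bw, ed=ed) == pytest.approx(factor * base)
        assert _point(bap=bap, ir=ir * factor, bw=bw, ed=ed) == pytest.approx(factor * base)
        assert _point(bap=bap, ir=ir, bw=bw * factor, ed=ed) == pytest.approx(base / factor)


def _config(**kw):
    defaults = dict(
        bap_eq_mg_per_kg=6.68e-4,
        ir_dist=FittedDistribution.constant(0.0452),
        bw_dist=FittedDistribution.constant(63.0),
        ed_dist=FittedDistribution.constant(5.0),
        n_iter=2000,
        seed=1,
    )
    defaults.update(kw)
    return CancerModelConfig(**defaults)


class TestCancerRiskMonteCarlo:
    def test_degenerate_inputs_equal_point_value(self):
        s = cancer_risk_monte_carlo(_config())
        assert s.mean == _point()
        assert s.sd == 0.0

    def test_uniform_ed_mean_matches_midpoint_value(self):
        """Risk is linear in ED, so E[risk] is the risk at ED = 7.5 yr."""
        n = 10_000
        s = cancer_risk_monte_carlo(
            _config(ed_dist=FittedDistribution.uniform(5.0, 10.0), n_iter=n, seed=2)
        )
        se = s.sd / np.sqrt(n)
        assert abs(s.mean - _point(ed=7.5)) < 3 * se

    def test_histogram_frequencies_sum_to_one(self):
        s = cancer_risk_monte_carlo(
            _config(
                ed_dist=FittedDistribution.uniform(5.0, 10.0),
                ir_dist=FittedDistribution.lognormal(np.log(0.045), 0.7),
                bw_dist=FittedDistribution.normal(63, 11, truncation=(0, 250)),
            )
        )
        assert s.histogram_freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_histogram_consistent_with_percentiles(self):
        """The median falls in a bin whose cumulative frequency brackets 0.5."""
        s = cancer_risk_monte_carlo(
            _config(ed_dist=FittedDistribution.uniform(5.0, 10.0), n_iter=5000)
        )
        cum = np.cumsum(s.histogram_freq)
        idx = np.searchsorted(s.histogram_edges[1:], s.p50)
        lo = cum[idx - 1] if idx > 0 else 0.0
        assert lo <= 0.5 + 1e-9 and cum[min(idx, len(cum) - 1)] >= 0.5 - 1e-9

    def test_deterministic_given_seed(self):
        cfg = _config(ed_dist=FittedDistribution.uniform(5.0, 10.0))
        a, b = cancer_risk_monte_carlo(cfg), cancer_risk_monte_carlo(cfg)
        assert a.mean == b.mean and a.p99 == b.p99

    def test_mean_converges_to_independence_product(self):
        """E[risk] = bap*365*osf/lifespan * E[IR] E[1/BW] E[ED]."""
        n = 20_000
        ir = FittedDistribution.uniform(0.02, 0.08)
        bw = FittedDistribution.normal(63, 11, truncation=(30, 120))
        ed = FittedDistribution.uniform(5.0, 10.0)
        cfg = _config(ir_dist=ir, bw_dist=bw, ed_dist=ed, n_iter=n, seed=5)
        s = cancer_risk_monte_carlo(cfg)
        bw_draws = bw.sample(200_000, seed=99)
        e_inv_bw = np.mean(1.0 / bw_draws)
        expected = 6.68e-4 * 365 * 7.3 / 28470 * 0.05 * e_inv_bw * 7.5
        se = s.sd / np.sqrt(n)
        assert abs(s.mean - expected) < 3 * se


class TestTieredRiskAnalysis:
    @pytest.fixture()
    def config(self):
        return _config(
            ir_dist=FittedDistribution.lognormal(np.log(0.045), 0.7),
            bw_dist=FittedDistribution.normal(63, 11, truncation=(0, 250)),
            ed_dist=FittedDistribution.uniform(5.0, 10.0),
            n_iter=4000,
            seed=3,
        )

    def test_percentiles_scale_exactly_with_tier_totals(self, meta, config):
        tiers = ("cpah7", "plus_unsubstituted", "plus_alkylated")
        out = tiered_risk_analysis(tiers, meta, config)
        totals = {t: censored_bap_equivalents(meta, t, 1.0) for t in tiers}
        base = out["cpah7"]
        for t in tiers[1:]:
            k = totals[t] / totals["cpah7"]
            for stat in ("mean", "p5", "p50", "p95", "p99"):
                assert getattr(out[t], stat) == pytest.approx(
                    k * getattr(base, stat), rel=1e-12
                )

    def test_alkylated_tier_raises_risk_by_factor_near_1p5(self, meta, config):
        out = tiered_risk_analysis(
            ("plus_unsubstituted", "plus_alkylated"), meta, config
        )
        for stat in ("mean", "p95"):
            ratio = getattr(out["plus_alkylated"], stat) / getattr(
                out["plus_unsubstituted"], stat
            )
            assert ratio == pytest.approx(1.5, abs=0.1)

    def test_single_tier_matches_direct_monte_carlo(self, meta, config):
        out = tiered_risk_analysis(("cpah7",), meta, config)
        direct_cfg = _config(
            bap_eq_mg_per_kg=censored_bap_equivalents(meta, "cpah7") * NG_PER_G_TO_PPM,
            ir_dist=config.ir_dist,
            bw_dist=config.bw_dist,
            ed_dist=config.ed_dist,
            n_iter=config.n_iter,
            seed=config.seed,
        )
        direct = cancer_risk_monte_carlo(direct_cfg)
        assert out["cpah7"].mean == pytest.approx(direct.mean, rel=1e-12)
        assert out["cpah7"].p95 == pytest.approx(direct.p95, rel=1e-12)

    def test_empty_tier_list_rejected(self, meta, config):
        with pytest.raises(ValidationError):
            tiered_risk_analysis((), meta, config)
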
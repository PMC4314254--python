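"""Nondetect substitution, homolog pooling, tier expansion, and
BaP-equivalent aggregation."""
import math

import numpy as np
import pandas as pd
import pytest

from pahrisk import (
    BAP_EQ_7CPAH_UG_PER_KG,
    CPAH7,
    MetadataError,
    ValidationError,
    bap_equivalents,
    censored_bap_equivalents,
    expand_analyte_tier,
    load_analyte_metadata,
    parent_totals,
    substitute_nondetects,
)

COLUMNS = ["sample_id", "analyte", "value_ng_per_g", "nondetect", "lod_ng_per_g"]


def conc(rows):
    return pd.DataFrame(rows, columns=COLUMNS)


class TestSubstituteNondetects:
    @pytest.mark.parametrize("lod,expected", [(10.0, 7.0711), (1.0, 0.70711)])
    def test_nondetect_maps_to_lod_over_sqrt2(self, lod, expected):
        df = conc([("s1", "naphthalene", math.nan, True, lod)])
        out = substitute_nondetects(df)
        assert out["value_ng_per_g"].iloc[0] == pytest.approx(expected, abs=5e-5)
        assert out["value_ng_per_g"].iloc[0] == lod / math.sqrt(2)

    def test_detected_value_passes_through(self):
        df = conc([("s1", "pyrene", 1.5, False, 2.0)])
        out = substitute_nondetects(df)
        assert out["value_ng_per_g"].iloc[0] == 1.5

    def test_substituted_value_strictly_below_lod(self):
        df = conc([("s1", "pyrene", math.nan, True, 3.0)])
        out = substitute_nondetects(df)
        assert 0 < out["value_ng_per_g"].iloc[0] < 3.0

    def test_nondetect_without_lod_names_sample_and_analyte(self):
        df = conc([("s9", "fluorene", math.nan, True, math.nan)])
        with pytest.raises(ValidationError, match="s9/fluorene"):
            substitute_nondetects(df)


class TestParentTotals:
    def test_homolog_added_to_parent(self, meta):
        df = substitute_nondetects(
            conc(
                [
                    ("s1", "naphthalene", 1.0, False, 2.0),
                    ("s1", "2-methylnaphthalene", 0.5, False, 2.0),
                ]
            )
        )
        totals = parent_totals(df, meta)
        row = totals[totals["rfd_group"] == "naphthalene"].iloc[0]
        assert row["total_ng_per_g"] == pytest.approx(1.5)
        assert row["rfd_mg_per_kg_day"] == 0.02

    def test_censored_parent_plus_detected_homolog(self, meta):
        df = substitute_nondetects(
            conc(
                [
                    ("s1", "naphthalene", math.nan, True, 1.0),
                    ("s1", "2-methylnaphthalene", 0.3, False, 2.0),
                ]
            )
        )
        totals = parent_totals(df, meta)
        assert totals["total_ng_per_g"].iloc[0] == pytest.approx(1.0 / math.sqrt(2) + 0.3)

    def test_analyte_without_rfd_group_excluded(self, meta):
        df = substitute_nondetects(conc([("s1", "perylene", 0.4, False, 3.0)]))
        assert len(parent_totals(df, meta)) == 0

    def test_anthracene_and_phenanthrene_pool_into_one_group(self, meta):
        df = substitute_nondetects(
            conc(
                [
                    ("s1", "anthracene", 0.2, False, 3.0),
                    ("s1", "phenanthrene", 0.3, False, 2.0),
                    ("s1", "1-methylphenanthrene", 0.1, False, 2.0),
                ]
            )
        )
        totals = parent_totals(df, meta)
        assert len(totals) == 1
        assert totals["rfd_group"].iloc[0] == "anthracene/phenanthrene"
        assert totals["total_ng_per_g"].iloc[0] == pytest.approx(0.6)

    def test_unknown_analyte_rejected(self, meta):
        df = substitute_nondetects(conc([("s1", "benzene", 0.4, False, 3.0)]))
        with pytest.raises(MetadataError, match="benzene"):
            parent_totals(df, meta)


class TestTierExpansion:
    def test_cpah7_is_exactly_the_seven_carcinogens(self, meta):
        assert set(expand_analyte_tier("cpah7", meta)) == set(CPAH7)
        assert len(expand_analyte_tier("cpah7", meta)) == 7

    def test_strict_set_inclusion_across_tiers(self, meta):
        t1 = set(expand_analyte_tier("cpah7", meta))
        t2 = set(expand_analyte_tier("plus_unsubstituted", meta))
        t3 = set(expand_analyte_tier("plus_alkylated", meta))
        assert t1 < t2 < t3

    def test_cpah_only_metadata_collapses_tiers(self, meta):
        small = meta[meta["class"] == "cpah7"].reset_index(drop=True)
        lists = [set(expand_analyte_tier(t, small)) for t in ("cpah7", "plus_unsubstituted", "plus_alkylated")]
        assert lists[0] == lists[1] == lists[2] == set(CPAH7)


class TestBapEquivalents:
    def test_bap_alone_is_identity(self, meta):
        df = substitute_nondetects(conc([("s1", "benzo[a]pyrene", 1.0, False, 1.0)]))
        assert bap_equivalents(df, meta, "cpah7").iloc[0] == pytest.approx(1.0)

    def test_weighted_sum(self, meta):
        # benzo[a]anthracene carries RPF 0.1, benzo[a]pyrene RPF 1
        df = substitute_nondetects(
            conc(
                [
                    ("s1", "benzo[a]anthracene", 2.0, False, 1.0),
                    ("s1", "benzo[a]pyrene", 1.0, False, 1.0),
                ]
            )
        )
        assert bap_equivalents(df, meta, "cpah7").iloc[0] == pytest.approx(1.2)

    def test_linearity_in_each_concentration(self, meta):
        df = substitute_nondetects(
            conc(
                [
                    ("s1", "benzo[a]pyrene", 1.0, False, 1.0),
                    ("s1", "chrysene", 3.0, False, 1.0),
                ]
            )
        )
        base = bap_equivalents(df, meta, "cpah7").iloc[0]
        df2 = df.copy()
        df2.loc[df2["analyte"] == "chrysene", "value_ng_per_g"] *= 2
        doubled = bap_equivalents(df2, meta, "cpah7").iloc[0]
        chrysene_contrib = 3.0 * 0.001
        assert doubled - base == pytest.approx(chrysene_contrib)

    def test_tier_monotonicity_for_fixed_concentrations(self, meta):
        rows = [("s1", a, 0.5, False, 1.0) for a in meta["analyte"]]
        df = substitute_nondetects(conc(rows))
        vals = [
            bap_equivalents(df, meta, t, default_rpf=1.0).iloc[0]
            for t in ("cpah7", "plus_unsubstituted", "plus_alkylated")
        ]
        assert vals[0] <= vals[1] <= vals[2]

    def test_negative_concentration_rejected(self, meta):
        df = conc([("s1", "benzo[a]pyrene", -1.0, False, 1.0)])
        with pytest.raises(ValidationError):
            bap_equivalents(df, meta, "cpah7")

    def test_missing_rpf_excluded_without_default(self, meta):
        # naphthalene has no accepted RPF: without a default it contributes 0
        df = substitute_nondetects(conc([("s1", "naphthalene", 5.0, False, 2.0)]))
        assert bap_equivalents(df, meta, "plus_unsubstituted").get("s1", 0.0) == 0.0
        with_default = bap_equivalents(df, meta, "plus_unsubstituted", default_rpf=1.0)
        assert with_default.iloc[0] == pytest.approx(5.0)


class TestCensoredTotals:
    def test_packaged_metadata_reproduces_published_7cpah_total(self, meta):
        assert censored_bap_equivalents(meta, "cpah7") == pytest.approx(
            BAP_EQ_7CPAH_UG_PER_KG, rel=1e-9
        )

    def test_censored_equals_explicit_all_nondetect_table(self, meta):
        """Desk value agrees with running a fully censored table through
        substitution + aggregation."""
        rows = [
            ("s1", a, math.nan, True, lod)
            for a, lod in zip(meta["analyte"], meta["lod_ng_per_g"])
        ]
        df = substitute_nondetects(conc(rows))
        via_table = bap_equivalents(df, meta, "plus_alkylated", default_rpf=1.0).iloc[0]
        desk = censored_bap_equivalents(meta, "plus_alkylated", default_rpf=1.0)
        assert via_table == pytest.approx(desk, rel=1e-12)
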
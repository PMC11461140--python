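import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloallom import (
    LengthMassAllometry,
    TraitRecord,
    aggregate,
    annual_clutch_volume,
    assemble_pair,
    clutch_volume,
    egg_volume_cm3,
    log10_table,
    mass_from_length,
    read_newick,
)
from phyloallom.traits import (
    InsufficientDataError,
    UnitMismatchError,
    UnresolvedAllometryError,
    build_trait_table,
    resolve_allometry,
)


def rec(trait, value=None, vmin=None, vmax=None, unit=None, sex="unspecified", sp="X"):
    return TraitRecord(sp, trait, value, vmin, vmax, unit, sex)


class TestAggregate:
    def test_mean_of_point_values(self):
        v, prov = aggregate([rec("clutch_size", 200), rec("clutch_size", 400)], "clutch_size")
        assert v == pytest.approx(300.0)
        assert prov == "mean"

    def test_range_midpoint(self):
        v, prov = aggregate([rec("svl", vmin=40, vmax=60, unit="mm")], "svl")
        assert v == pytest.approx(50.0)
        assert "midpoint" in prov

    def test_longevity_keeps_maximum(self):
        v, prov = aggregate(
            [rec("max_longevity", 5), rec("max_longevity", 9)], "max_longevity"
        )
        assert v == pytest.approx(9.0)
        assert "max" in prov

    def test_female_records_preferred_for_body_size(self):
        recs = [
            rec("body_mass", 10, sex="male"),
            rec("body_mass", 6, sex="female"),
            rec("body_mass", 30),
        ]
        v, prov = aggregate(recs, "body_mass")
        assert v == pytest.approx(6.0)
        assert "female-preferred" in prov

    def test_female_preference_not_applied_to_clutch_traits(self):
        recs = [rec("clutch_size", 100, sex="female"), rec("clutch_size", 300)]
        v, _ = aggregate(recs, "clutch_size")
        assert v == pytest.approx(200.0)

    def test_mixed_units_rejected(self):
        recs = [rec("svl", 40, unit="mm"), rec("svl", 4, unit="cm")]
        with pytest.raises(UnitMismatchError):
            aggregate(recs, "svl")

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate([], "clutch_size")

    @given(st.permutations(list(range(5))))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance(self, perm):
        base = [rec("clutch_size", float(10 + 7 * i)) for i in range(5)]
        shuffled = [base[i] for i in perm]
        assert aggregate(shuffled, "clutch_size")[0] == pytest.approx(
            aggregate(base, "clutch_size")[0]
        )


class TestDerivedVolumes:
    def test_egg_volume_two_mm(self):
        assert egg_volume_cm3(2.0) == pytest.approx((math.pi / 6) * 8 / 1000, rel=0, abs=0)

    def test_egg_volume_one_mm(self):
        assert egg_volume_cm3(1.0) == pytest.approx(5.236e-4, rel=1e-3)

    def test_products(self):
        assert clutch_volume(0.004, 100) == pytest.approx(0.4)
        assert clutch_volume(0.123, 1) == pytest.approx(0.123)
        assert annual_clutch_volume(0.4, 2) == pytest.approx(0.8)
        assert annual_clutch_volume(clutch_volume(egg_volume_cm3(2.0), 250), 3) == pytest.approx(
            3.14159, rel=1e-4
        )

    @pytest.mark.parametrize("fn", [egg_volume_cm3, lambda v: clutch_volume(v, 1)])
    def test_nonpositive_inputs_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0)

    @given(
        st.floats(0.5, 10), st.floats(1, 1e4), st.floats(0.5, 12)
    )
    @settings(max_examples=50, deadline=None)
    def test_log_additivity_of_volume_chain(self, d, cs, cpy):
        ev = egg_volume_cm3(d)
        acv = annual_clutch_volume(clutch_volume(ev, cs), cpy)
        assert math.log10(acv) == pytest.approx(
            math.log10(ev) + math.log10(cs) + math.log10(cpy), abs=1e-12
        )


class TestMassFromLength:
    def test_power_law(self):
        assert mass_from_length(2.0, LengthMassAllometry("g", 1.0, 3.0)) == pytest.approx(8.0)
        assert mass_from_length(10.0, LengthMassAllometry("g", 0.05, 2.5)) == pytest.approx(
            15.811, rel=1e-3
        )

    def test_family_preferred_then_fallback(self):
        table = {
            "Ranidae": LengthMassAllometry("Ranidae", 1.0, 3.0),
            "aquatic": LengthMassAllometry("aquatic", 2.0, 2.0),
        }
        assert resolve_allometry("Ranidae", "aquatic", table).group == "Ranidae"
        assert resolve_allometry("Bufonidae", "aquatic", table).group == "aquatic"
        with pytest.raises(UnresolvedAllometryError):
            resolve_allometry("Bufonidae", "arboreal", table)

    def test_nonpositive_coefficient_rejected(self):
        with pytest.raises(ValueError):
            LengthMassAllometry("g", -1.0, 3.0)


class TestTableOps:
    def test_log10_values_and_missing_preserved(self):
        df = pd.DataFrame({"a": [100.0, 1.0], "b": [10.0, np.nan]}, index=["s1", "s2"])
        out = log10_table(df)
        assert out.loc["s1", "a"] == pytest.approx(2.0)
        assert out.loc["s2", "a"] == pytest.approx(0.0)
        assert np.isnan(out.loc["s2", "b"])

    def test_log10_nonpositive_names_cell(self):
        df = pd.DataFrame({"a": [1.0, 0.0]}, index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            log10_table(df)

    def test_build_trait_table_wide_shape(self):
        records = [
            rec("body_mass", 10, sp="A"),
            rec("body_mass", 20, sp="B"),
            rec("clutch_size", 100, sp="A"),
        ]
        table, prov = build_trait_table(records)
        assert table.shape == (2, 2)
        assert np.isnan(table.loc["B", "clutch_size"])
        assert prov.loc["A", "clutch_size"] == "mean"


class TestAssemblePair:
    tree = staticmethod(lambda: read_newick("((A:1,B:1):1,(C:1,(D:0.5,E:0.5):0.5):1);"))

    def test_complete_case_count(self):
        df = pd.DataFrame(
            {
                "x": [1.0, 2.0, 3.0, 4.0, 5.0],
                "y": [1.0, np.nan, 3.0, np.nan, 5.0],
            },
            index=list("ABCDE"),
        )
        x, y, pruned, dropped = assemble_pair(df, "x", "y", self.tree())
        assert len(x) == len(y) == pruned.n_tips == 3
        assert set(pruned.tip_labels) == {"A", "C", "E"}
        assert dropped == []

    def test_species_outside_tree_dropped(self):
        df = pd.DataFrame(
            {"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4]}, index=["A", "B", "C", "ZZ"]
        )
        x, y, pruned, dropped = assemble_pair(df, "x", "y", self.tree())
        assert dropped == ["ZZ"]
        assert pruned.n_tips == 3

    def test_order_matches_pruned_tips(self):
        df = pd.DataFrame(
            {"x": [1.0, 2, 3, 4, 5], "y": [10.0, 20, 30, 40, 50]}, index=list("ABCDE")
        )
        x, y, pruned, _ = assemble_pair(df, "x", "y", self.tree())
        for xi, yi, lab in zip(x, y, pruned.tip_labels):
            assert df.loc[lab, "x"] == xi and df.loc[lab, "y"] == yi

    def test_insufficient_data_raises(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [np.nan] * 3}, index=list("ABC"))
        with pytest.raises(InsufficientDataError):
            assemble_pair(df, "x", "y", self.tree())
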
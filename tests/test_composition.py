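"""Composition, unsaturation-index, and fatty-acid decomposition metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidheat import (
    Unit,
    class_composition,
    fatty_acid_fold_change,
    pc_18_3_to_18_2_ratio,
    species_composition,
    tag_pc_ratio,
    unsaturation_index_class,
    unsaturation_index_species,
)
from lipidheat.composition import MAJOR_FATTY_ACIDS, fatty_acid_totals
from lipidheat.dataset import DatasetError
from lipidheat.nomenclature import (
    AcylChain,
    Headgroup,
    assigned_chains,
    parse_lipid_name,
)

from conftest import make_dataset


def pct_ds(values, meta=None):
    return make_dataset(values, meta, unit=Unit.PERCENT)


# -- class & species composition ------------------------------------------

def test_class_composition_direct_sums():
    ds = pct_ds({"PC(34:3)": [30.0], "PC(34:2)": [20.0], "TAG(52:3)": [50.0]})
    out = class_composition(ds)
    assert out.loc["all", "PC"] == pytest.approx(50.0)
    assert out.loc["all", "TAG"] == pytest.approx(50.0)


def test_class_composition_partitions_total(default_pct):
    out = class_composition(default_pct, by=["genotype", "treatment"])
    np.testing.assert_allclose(out.sum(axis=1), 100.0, atol=1e-6)


def test_class_composition_invariant_to_column_order(default_pct):
    shuffled = default_pct.select_analytes(default_pct.analyte_names[::-1])
    a = class_composition(default_pct, by=["treatment"])
    b = class_composition(shuffled, by=["treatment"])
    pd.testing.assert_frame_equal(a.sort_index(axis=1), b.sort_index(axis=1))


def test_species_composition_single_key():
    ds = pct_ds({"PC(34:3)": [1.0], "PE(34:3)": [3.0], "TAG(52:3)": [96.0]})
    out = species_composition(ds)
    assert list(out.columns) == ["34:3"]
    assert out.iloc[0, 0] == pytest.approx(100.0)


def test_species_composition_sums_to_100(default_pct):
    out = species_composition(default_pct, by=["genotype", "treatment"])
    np.testing.assert_allclose(out.sum(axis=1), 100.0, atol=1e-6)


def test_species_composition_empty_selection_errors():
    ds = pct_ds({"TAG(52:3)": [100.0]})
    with pytest.raises(DatasetError):
        species_composition(ds, classes={Headgroup.PC})


def test_dominant_species_cover_most_of_template(default_pct):
    """The five dominant diacyl species carry >= 85% of the structural
    glycerolipid signal under ambient temperature, as in peanut anthers."""
    at = default_pct.values.loc[default_pct.meta["treatment"] == "AT"]
    sub = default_pct.__class__(at, default_pct.meta.loc[at.index], default_pct.unit)
    out = species_composition(sub)
    top5 = out[["34:3", "34:2", "36:6", "36:5", "36:4"]].sum(axis=1)
    assert (top5 >= 85.0).all() and (top5 <= 92.0).all()


# -- unsaturation index ----------------------------------------------------

@pytest.mark.parametrize(
    "name, expected",
    [("PC(36:6)", 3.0), ("TAG(18:2/16:0/18:1)", 1.0), ("PE(34:0)", 0.0),
     ("SE(18:1)", 1.0)],
)
def test_unsaturation_index_species(name, expected):
    assert unsaturation_index_species(parse_lipid_name(name)) == expected


def test_unsaturation_index_undefined_for_sg():
    with pytest.raises(DatasetError):
        unsaturation_index_species(parse_lipid_name("SG"))


def test_unsaturation_index_class_weighted_mean():
    ds = pct_ds({"PC(34:3)": [2.0], "PC(36:6)": [1.0], "TAG(52:3)": [97.0]})
    out = unsaturation_index_class(ds, Headgroup.PC)
    assert out["all"] == pytest.approx((1.5 * 2 + 3.0 * 1) / 3)


def test_unsaturation_index_single_species_class():
    ds = pct_ds({"PC(34:3)": [5.0], "PE(36:5)": [95.0]})
    out = unsaturation_index_class(ds, Headgroup.PE)
    assert out["all"] == pytest.approx(2.5)


def test_unsaturation_index_scale_invariance():
    a = make_dataset({"PC(34:3)": [2.0], "PC(36:6)": [1.0]})
    b = make_dataset({"PC(34:3)": [20.0], "PC(36:6)": [10.0]})
    assert unsaturation_index_class(a, Headgroup.PC)["all"] == pytest.approx(
        unsaturation_index_class(b, Headgroup.PC)["all"]
    )


@settings(max_examples=40, derandomize=True)
@given(
    amounts=st.lists(st.floats(min_value=0.0, max_value=10.0), min_size=4, max_size=4)
)
def test_unsaturation_index_matches_brute_force(amounts):
    names = ["PC(34:3)", "PC(34:2)", "PC(36:6)", "PC(36:5)"]
    if sum(amounts) == 0:
        amounts[0] = 1.0
    ds = make_dataset({n: [a] for n, a in zip(names, amounts)})
    out = unsaturation_index_class(ds, Headgroup.PC)["all"]
    # explicit loop over species
    num = den = 0.0
    for n, a in zip(names, amounts):
        sp = parse_lipid_name(n)
        num += (sp.total_double_bonds / sp.chain_count) * a
        den += a
    assert out == pytest.approx(num / den)
    indices = [unsaturation_index_species(parse_lipid_name(n)) for n in names]
    assert min(indices) - 1e-12 <= out <= max(indices) + 1e-12


def test_class_index_bounded_by_member_species(default_pct):
    for hg in (Headgroup.PC, Headgroup.PE, Headgroup.TAG):
        idx = [unsaturation_index_species(sp) for sp in default_pct.species
               if sp.headgroup is hg]
        out = unsaturation_index_class(default_pct, hg, by=["treatment"])
        assert (out >= min(idx) - 1e-9).all() and (out <= max(idx) + 1e-9).all()


# -- fatty-acid decomposition ---------------------------------------------

def test_fatty_acid_totals_di_18_3():
    ds = make_dataset({"PC(36:6)": [1.0]})
    table = fatty_acid_totals(ds, Headgroup.PC)
    assert table.amounts["18:3"] == pytest.approx(2.0)
    assert table.amounts.drop("18:3").eq(0).all()
    assert table.excluded == []


def test_fatty_acid_totals_excludes_ambiguous():
    ds = make_dataset({"PC(36:4)": [1.0]})
    table = fatty_acid_totals(ds, Headgroup.PC)
    assert table.amounts.eq(0).all()
    assert table.excluded == ["PC(36:4)"]


def test_fatty_acid_totals_tag_54_5_excluded():
    ds = make_dataset({"TAG(18:2/16:0/18:1)": [1.0], "TAG(54:5)": [1.0]})
    table = fatty_acid_totals(ds, Headgroup.TAG)
    assert table.excluded == ["TAG(54:5)"]
    assert table.amounts["16:0"] == pytest.approx(1.0)


@settings(max_examples=30, derandomize=True)
@given(
    amounts=st.lists(st.floats(min_value=0.0, max_value=5.0), min_size=3, max_size=3)
)
def test_fatty_acid_totals_matches_per_chain_enumeration(amounts):
    names = ["TAG(18:2/16:0/18:1)", "TAG(18:2/18:2/16:0)", "TAG(16:0/18:3/18:2)"]
    ds = make_dataset({n: [a] for n, a in zip(names, amounts)})
    table = fatty_acid_totals(ds, Headgroup.TAG)
    for fa in MAJOR_FATTY_ACIDS:
        expected = 0.0
        for n, a in zip(names, amounts):
            for ch in assigned_chains(parse_lipid_name(n)):
                if ch == fa:
                    expected += a
        assert table.amounts[str(fa)] == pytest.approx(expected)


def test_fold_change_identity_and_halved_18_3():
    at = {"PC(34:3)": 2.0, "PC(34:2)": 2.0, "PC(36:6)": 1.0, "PC(34:1)": 1.0}
    meta = {"treatment": ["AT", "AT", "HT", "HT"]}
    same = make_dataset({k: [v, v, v, v] for k, v in at.items()}, meta)
    table = fatty_acid_fold_change(same, Headgroup.PC)
    present = table.amounts > 0
    np.testing.assert_allclose(table.fold_change[present], 1.0)

    # HT halves every 18:3-containing species: 18:3 fold 0.5, others untouched
    halved = make_dataset(
        {"PC(34:3)": [2.0, 2.0, 1.0, 1.0], "PC(34:2)": [2.0, 2.0, 2.0, 2.0],
         "PC(36:6)": [1.0, 1.0, 0.5, 0.5], "PC(34:1)": [1.0, 1.0, 1.0, 1.0]},
        meta,
    )
    table = fatty_acid_fold_change(halved, Headgroup.PC)
    assert table.fold_change["18:3"] == pytest.approx(0.5)
    assert table.fold_change["18:2"] == pytest.approx(1.0)
    assert table.fold_change["18:1"] == pytest.approx(1.0)


def test_fold_change_scale_invariance():
    meta = {"treatment": ["AT", "AT", "HT", "HT"]}
    base = {"PC(34:3)": [2.0, 3.0, 1.0, 1.5], "PC(34:2)": [2.0, 2.0, 2.5, 2.0]}
    a = fatty_acid_fold_change(make_dataset(base, meta), Headgroup.PC)
    b = fatty_acid_fold_change(
        make_dataset({k: [7.0 * x for x in v] for k, v in base.items()}, meta),
        Headgroup.PC,
    )
    present = a.amounts > 0
    np.testing.assert_allclose(a.fold_change[present], b.fold_change[present])


def test_fold_change_zero_at_denominator_flagged():
    meta = {"treatment": ["AT", "HT"]}
    with pytest.raises(DatasetError):
        fatty_acid_fold_change(make_dataset({"PC(34:3)": [1.0, 1.0]}, meta),
                               Headgroup.PC, genotype="nope")
    ds = make_dataset({"PC(34:1)": [1.0, 1.0, 1.0, 1.0]},
                      {"treatment": ["AT", "AT", "HT", "HT"]})
    table = fatty_acid_fold_change(ds, Headgroup.PC)
    assert np.isnan(table.fold_change["18:3"])  # AT sum of 18:3 is zero


# -- ratios ----------------------------------------------------------------

def test_pc_ratio_occurrence_counting():
    # 36:6 = 18:3/18:3, 36:5 = 18:2/18:3 -> 18:3 total 3, 18:2 total 1
    ds = make_dataset({"PC(36:6)": [1.0], "PC(36:5)": [1.0]})
    out = pc_18_3_to_18_2_ratio(ds)
    assert out["all"] == pytest.approx(3.0)


def test_pc_ratio_zero_numerator_and_undefined():
    ds = make_dataset({"PC(34:2)": [1.0], "PC(34:1)": [1.0]})
    assert pc_18_3_to_18_2_ratio(ds)["all"] == pytest.approx(0.0)
    ambiguous = make_dataset({"PC(36:4)": [1.0]})
    assert np.isnan(pc_18_3_to_18_2_ratio(ambiguous)["all"])


def test_tag_pc_ratio_direct_and_invariant_to_normalization():
    ds = make_dataset({"TAG(52:3)": [20.0], "PC(34:3)": [30.0], "PC(34:2)": [10.0]})
    assert tag_pc_ratio(ds)["all"] == pytest.approx(0.5)
    from lipidheat import percent_of_total

    assert tag_pc_ratio(percent_of_total(ds))["all"] == pytest.approx(0.5)


def test_tag_pc_ratio_zero_pc_errors():
    ds = make_dataset({"TAG(52:3)": [20.0], "PC(34:3)": [0.0]})
    with pytest.raises(DatasetError, match="s1"):
        tag_pc_ratio(ds)
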
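"""Factorial LS means, AT-vs-HT flags, and compact letter displays."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lipidheat.groupstats import DesignError, DesignSpec, FactorialLSD, fit_cell_means


def balanced_design(effects=None, noise=None, genotypes=("A", "B"), reps=2,
                    years=(2018, 2019), blocks=(1, 2)):
    """Fully crossed design; effects maps (genotype, treatment) -> mean."""
    rows = []
    i = 0
    for g in genotypes:
        for t in ("AT", "HT"):
            mu = 0.0 if effects is None else effects[(g, t)]
            for y in years:
                for b in blocks:
                    for r in range(reps):
                        eps = 0.0 if noise is None else noise[i]
                        rows.append({"genotype": g, "treatment": t, "year": y,
                                     "block": b, "replicate": r, "value": mu + eps})
                        i += 1
    return pd.DataFrame(rows)


def test_balanced_ls_means_equal_raw_cell_means():
    rng = np.random.default_rng(42)
    df = balanced_design()
    df["value"] = rng.normal(size=len(df))
    res = FactorialLSD(df).fit()
    raw = df.groupby(["genotype", "treatment"])["value"].mean()
    for (g, t), row in res.cell_means.iterrows():
        assert row["lsmean"] == pytest.approx(raw[(g, t)], abs=1e-9)


def test_year_shift_leaves_treatment_contrasts_unchanged():
    rng = np.random.default_rng(7)
    df = balanced_design(effects={("A", "AT"): 1.0, ("A", "HT"): 2.0,
                                  ("B", "AT"): 0.0, ("B", "HT"): 0.5})
    df["value"] += rng.normal(0, 0.3, size=len(df))
    res1 = FactorialLSD(df).fit()
    shifted = df.copy()
    shifted.loc[shifted["year"] == 2019, "value"] += 100.0
    res2 = FactorialLSD(shifted).fit()
    for g in ("A", "B"):
        d1 = (res1.cell_means.loc[(g, "HT"), "lsmean"]
              - res1.cell_means.loc[(g, "AT"), "lsmean"])
        d2 = (res2.cell_means.loc[(g, "HT"), "lsmean"]
              - res2.cell_means.loc[(g, "AT"), "lsmean"])
        assert d1 == pytest.approx(d2, abs=1e-8)
    assert res1.sigma2 == pytest.approx(res2.sigma2, abs=1e-8)


def test_unbalanced_ls_means_match_normal_equations_oracle():
    """Drop one observation and compare with a direct least-squares solve on
    an explicitly constructed dummy design."""
    rng = np.random.default_rng(3)
    df = balanced_design()
    df["value"] = rng.normal(size=len(df))
    df = df.drop(index=df.index[5]).reset_index(drop=True)
    res = FactorialLSD(df).fit()

    # brute-force design matrix: intercept + dummies for every factor level
    def row_features(r):
        return [
            1.0,
            1.0 if r.treatment == "HT" else 0.0,
            1.0 if r.genotype == "B" else 0.0,
            1.0 if (r.treatment == "HT" and r.genotype == "B") else 0.0,
            1.0 if r.year == 2019 else 0.0,
            1.0 if (r.year == 2018 and r.block == 2) else 0.0,
            1.0 if (r.year == 2019 and r.block == 2) else 0.0,
        ]

    X = np.array([row_features(r) for r in df.itertuples()])
    beta = np.linalg.solve(X.T @ X, X.T @ df["value"].to_numpy())

    def lsmean(g, t):
        grid = [
            row_features(type("R", (), {"treatment": t, "genotype": g,
                                        "year": y, "block": b})())
            for y, b in itertools.product((2018, 2019), (1, 2))
        ]
        return float(np.mean(np.array(grid) @ beta))

    for (g, t), row in res.cell_means.iterrows():
        assert row["lsmean"] == pytest.approx(lsmean(g, t), abs=1e-8)


def test_cell_with_too_few_observations_rejected():
    df = balanced_design(reps=1, years=(2018,), blocks=(1,))
    with pytest.raises(DesignError, match="< 2 observations"):
        FactorialLSD(df)


def test_at_vs_ht_no_flags_when_identical():
    df = balanced_design(effects={(g, t): 1.0 for g in "AB" for t in ("AT", "HT")})
    res = FactorialLSD(df).fit()
    flags = res.at_vs_ht()
    assert not flags["significant"].any()


def test_at_vs_ht_planted_large_effect_flagged():
    rng = np.random.default_rng(11)
    df = balanced_design(effects={("A", "AT"): 0.0, ("A", "HT"): 10.0,
                                  ("B", "AT"): 0.0, ("B", "HT"): 0.0})
    df["value"] += rng.normal(0, 1.0, size=len(df))
    flags = FactorialLSD(df).fit().at_vs_ht()
    assert bool(flags.loc["A", "significant"])
    assert flags.loc["A", "diff_ht_minus_at"] > 5


def test_flags_invariant_to_response_rescaling():
    rng = np.random.default_rng(5)
    df = balanced_design(effects={("A", "AT"): 0.0, ("A", "HT"): 1.0,
                                  ("B", "AT"): 0.0, ("B", "HT"): 0.2})
    df["value"] += rng.normal(0, 0.5, size=len(df))
    f1 = FactorialLSD(df).fit().at_vs_ht()
    df2 = df.copy()
    df2["value"] *= 1234.5
    f2 = FactorialLSD(df2).fit().at_vs_ht()
    pd.testing.assert_series_equal(f1["significant"], f2["significant"])
    np.testing.assert_allclose(f1["t"], f2["t"], atol=1e-8)


def test_pooled_treatment_effect_direction_and_significance():
    rng = np.random.default_rng(17)
    df = balanced_design(effects={("A", "AT"): 0.0, ("A", "HT"): -2.0,
                                  ("B", "AT"): 0.0, ("B", "HT"): -2.0})
    df["value"] += rng.normal(0, 0.5, size=len(df))
    eff = FactorialLSD(df).fit().treatment_effect()
    assert eff["diff_ht_minus_at"] < 0
    assert eff["significant"]


# -- compact letter display ------------------------------------------------

def test_letters_all_equal_means_share_a():
    df = balanced_design(effects={(g, t): 2.0 for g in "AB" for t in ("AT", "HT")})
    res = FactorialLSD(df).fit()
    letters = res.lsd_letters(within="AT")
    assert set(letters) == {"a"}


def test_letters_two_separated_levels():
    rng = np.random.default_rng(2)
    df = balanced_design(effects={("A", "AT"): 10.0, ("A", "HT"): 10.0,
                                  ("B", "AT"): 0.0, ("B", "HT"): 0.0})
    df["value"] += rng.normal(0, 0.5, size=len(df))
    letters = FactorialLSD(df).fit().lsd_letters(within="AT")
    assert letters["A"] == "a" and letters["B"] == "b"


def test_letters_invariant_to_level_order():
    rng = np.random.default_rng(9)
    effects = {("A", "AT"): 3.0, ("B", "AT"): 0.0, ("C", "AT"): 2.8}
    effects.update({(g, "HT"): v for (g, _), v in effects.items()})
    df = balanced_design(effects=effects, genotypes=("A", "B", "C"))
    df["value"] += rng.normal(0, 0.5, size=len(df))
    res = FactorialLSD(df).fit()
    a = res.lsd_letters(within="AT", levels=["A", "B", "C"])
    b = res.lsd_letters(within="AT", levels=["C", "A", "B"])
    assert a.sort_index().equals(b.sort_index())


def test_letters_chain_overlap():
    """A > C > B with only the extreme pair significant gives overlapping
    letters (A: a, C: ab, B: b)."""
    rng = np.random.default_rng(21)
    effects = {("A", "AT"): 1.0, ("C", "AT"): 0.55, ("B", "AT"): 0.0}
    effects.update({(g, "HT"): v for (g, _), v in effects.items()})
    df = balanced_design(effects=effects, genotypes=("A", "B", "C"))
    df["value"] += rng.normal(0, 0.55, size=len(df))
    res = FactorialLSD(df).fit()
    letters = res.lsd_letters(within="AT")
    sig = res._lsd_significant
    # verify the lettering is consistent with the pairwise LSD matrix
    cm = res.cell_means.xs("AT", level="treatment")
    for x, y in itertools.combinations(cm.index, 2):
        share = bool(set(letters[x]) & set(letters[y]))
        significant = sig(cm.loc[x, "lsmean"], cm.loc[x, "n"],
                          cm.loc[y, "lsmean"], cm.loc[y, "n"])
        assert share == (not significant)


# -- calibration properties -----------------------------------------------

def test_ls_means_unbiased_on_balanced_synthetic_data():
    """Mean of LS-mean estimates over 200 simulations hits the true cell
    means within Monte-Carlo error."""
    truth = {("A", "AT"): 1.0, ("A", "HT"): 0.4, ("B", "AT"): -0.3, ("B", "HT"): 0.1}
    rng = np.random.default_rng(123)
    sums = {k: 0.0 for k in truth}
    n_sim = 200
    for _ in range(n_sim):
        df = balanced_design(effects=truth)
        df["value"] += rng.normal(0, 1.0, size=len(df))
        res = FactorialLSD(df).fit()
        for k in truth:
            sums[k] += res.cell_means.loc[k, "lsmean"]
    se = 1.0 / np.sqrt(16 * n_sim)  # sd/sqrt(n_cell * n_sim)
    for k, v in truth.items():
        assert sums[k] / n_sim == pytest.approx(v, abs=4 * se)


def test_design_spec_validates_alpha():
    with pytest.raises(DesignError):
        DesignSpec(alpha=1.5)


def test_functional_wrapper_and_summary():
    df = balanced_design(effects={("A", "AT"): 1.0, ("A", "HT"): 0.0,
                                  ("B", "AT"): 1.0, ("B", "HT"): 0.0})
    rng = np.random.default_rng(1)
    df["value"] += rng.normal(0, 0.1, size=len(df))
    res = fit_cell_means(df)
    text = res.summary()
    assert "Fisher" in text and "AT vs HT" in text


def test_benjamini_hochberg_is_more_conservative():
    from lipidheat.groupstats import benjamini_hochberg

    p = pd.Series([0.001, 0.04, 0.045, 0.8, np.nan],
                  index=list("abcde"))
    adj = benjamini_hochberg(p, alpha=0.05)
    raw = p < 0.05
    assert adj["a"]                       # strong signal survives
    assert not adj["e"]                   # missing p -> not significant
    assert adj.sum() <= raw.sum()         # never flags more than unadjusted
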
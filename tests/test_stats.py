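"""Factorial ANOVA, per-condition t-tests, representative selection."""

import numpy as np
import pandas as pd
import pytest

from conftest import pooled_t_oracle, sequential_anova_oracle
from cotyquant import stats as st


def _cohort(day_levels, genotypes, n_per_cell, rng, effects=None):
    rows = []
    effects = effects or {}
    for d in day_levels:
        for g in genotypes:
            n = n_per_cell[(d, g)] if isinstance(n_per_cell, dict) else n_per_cell
            mu = effects.get((d, g), 0.0)
            for _ in range(n):
                rows.append({"day": d, "genotype": g, "y": rng.normal(mu, 1.0)})
    return pd.DataFrame(rows)


def test_anova_matches_design_matrix_oracle_balanced():
    rng = np.random.default_rng(1)
    table = _cohort([4, 5, 6], ["Col-0", "gsl10-5"], 4, rng,
                    effects={(6, "gsl10-5"): 2.0})
    res = st.two_way_anova(table, "y")
    oracle = sequential_anova_oracle(table["day"], table["genotype"], table["y"])
    for term in ("day", "genotype", "day:genotype"):
        row = res.table.loc[term]
        np.testing.assert_allclose(row["sum_sq"], oracle[term]["ss"], rtol=1e-8)
        np.testing.assert_allclose(row["F"], oracle[term]["F"], rtol=1e-8)
        np.testing.assert_allclose(row["p"], oracle[term]["p"], rtol=1e-8)
        assert row["df"] == oracle[term]["df"]
    np.testing.assert_allclose(
        res.table.loc["residual", "sum_sq"], oracle["residual"]["ss"], rtol=1e-8
    )


def test_anova_matches_oracle_unbalanced():
    rng = np.random.default_rng(2)
    ns = {(4, "a"): 6, (4, "b"): 3, (5, "a"): 4, (5, "b"): 8}
    table = _cohort([4, 5], ["a", "b"], ns, rng, effects={(5, "b"): 1.0})
    res = st.two_way_anova(table, "y")
    oracle = sequential_anova_oracle(table["day"], table["genotype"], table["y"])
    for term in ("day", "genotype", "day:genotype"):
        np.testing.assert_allclose(
            res.table.loc[term, "sum_sq"], oracle[term]["ss"], rtol=1e-8
        )
        np.testing.assert_allclose(res.table.loc[term, "p"], oracle[term]["p"], rtol=1e-8)


def test_anova_ss_decomposition_sums_to_total():
    rng = np.random.default_rng(3)
    table = _cohort([4, 5, 6, 7], ["a", "b"], 5, rng, effects={(7, "b"): 1.5})
    res = st.two_way_anova(table, "y")
    total = ((table["y"] - table["y"].mean()) ** 2).sum()
    np.testing.assert_allclose(res.table["sum_sq"].sum(), total, rtol=1e-8)


def test_anova_balanced_sequential_equals_marginal():
    rng = np.random.default_rng(4)
    table = _cohort([4, 5], ["a", "b"], 6, rng, effects={(5, "a"): 0.7})
    seq = st.two_way_anova(table, "y", ss="sequential")
    marg = st.two_way_anova(table, "y", ss="marginal")
    for term in ("day", "genotype", "day:genotype"):
        np.testing.assert_allclose(
            seq.table.loc[term, "sum_sq"], marg.table.loc[term, "sum_sq"], rtol=1e-8
        )


def test_anova_zero_variance_is_flagged_not_fatal():
    table = _cohort([4, 5], ["a", "b"], 3, np.random.default_rng(0))
    table["y"] = 7.0
    res = st.two_way_anova(table, "y")
    assert res.degenerate
    assert np.isnan(res.table.loc["genotype", "F"])
    np.testing.assert_allclose(res.table.loc["day", "sum_sq"], 0.0, atol=1e-20)


def test_anova_empty_cell_is_an_error():
    table = _cohort([4, 5], ["a", "b"], 3, np.random.default_rng(0))
    table = table[~((table["day"] == 5) & (table["genotype"] == "b"))]
    with pytest.raises(ValueError, match="empty cells"):
        st.two_way_anova(table, "y")


def test_anova_requires_two_levels_and_replication():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="levels"):
        st.two_way_anova(_cohort([4], ["a", "b"], 3, rng), "y")
    with pytest.raises(ValueError, match="replication"):
        st.two_way_anova(_cohort([4, 5], ["a", "b"], 1, rng), "y")


def test_ttest_identical_samples():
    table = pd.DataFrame(
        {
            "genotype": ["a"] * 3 + ["b"] * 3,
            "ca_mM": 0.2,
            "day": 5,
            "y": [1.0, 2.0, 3.0] * 2,
        }
    )
    out = st.t_test_per_condition(table, "y")
    row = out.iloc[0]
    assert row["t"] == 0.0 and row["p"] == 1.0 and row["stars"] == "ns"


def test_ttest_matches_closed_form():
    x1, x2 = [1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0]
    table = pd.DataFrame(
        {
            "genotype": ["a"] * 4 + ["b"] * 4,
            "ca_mM": 0.1,
            "day": 6,
            "y": x1 + x2,
        }
    )
    out = st.t_test_per_condition(table, "y")
    t_exp, p_exp = pooled_t_oracle(x1, x2)
    row = out.iloc[0]
    assert row["t"] == pytest.approx(t_exp, rel=1e-12)
    assert row["p"] == pytest.approx(p_exp, rel=1e-12)
    assert row["df"] == 6


def test_ttest_skips_undersized_cells():
    table = pd.DataFrame(
        {
            "genotype": ["a", "a", "b"] + ["a", "a", "b", "b"],
            "ca_mM": [0.2] * 3 + [0.1] * 4,
            "day": 5,
            "y": np.arange(7, dtype=float),
        }
    )
    out = st.t_test_per_condition(table, "y")
    assert len(out) == 1 and out.iloc[0]["ca_mM"] == 0.1


@pytest.mark.parametrize(
    "p,stars",
    [(0.0009, "***"), (0.001, "**"), (0.009, "**"), (0.01, "*"), (0.049, "*"),
     (0.05, "ns"), (0.5, "ns")],
)
def test_star_thresholds(p, stars):
    assert st.p_to_stars(p) == stars


def _triple_table(triples, ids=None, **meta):
    ids = ids or [f"s{i}" for i in range(len(triples))]
    return pd.DataFrame(
        [
            {
                "image_id": i,
                "genotype": meta.get("genotype", "a"),
                "ca_mM": meta.get("ca_mM", 0.2),
                "day": meta.get("day", 5),
                "largest_spot_area_px": t[0],
                "x_rel": t[1],
                "y_rel": t[2],
            }
            for i, t in zip(ids, triples)
        ]
    )


def test_representative_single_sample():
    out = st.select_representative(_triple_table([(1000, 0.0, 0.5)]))
    assert out.iloc[0]["image_id"] == "s0"


def test_representative_hand_worked_medians():
    table = _triple_table([(1000, 0.0, 0.5), (1200, 0.1, 0.6), (5000, 0.4, -0.2)])
    out = st.select_representative(table)
    # medians (1200, 0.1, 0.5); sample 2 scores sqrt(0.01)
    assert out.iloc[0]["image_id"] == "s1"
    assert out.iloc[0]["score"] == pytest.approx(0.1)


def test_representative_translation_invariance():
    table = _triple_table([(1000, 0.0, 0.5), (1200, 0.1, 0.6), (5000, 0.4, -0.2)])
    shifted = table.assign(largest_spot_area_px=table["largest_spot_area_px"] + 777)
    assert (
        st.select_representative(table).iloc[0]["image_id"]
        == st.select_representative(shifted).iloc[0]["image_id"]
    )


def test_representative_tie_breaks_to_smallest_id():
    table = _triple_table([(1000, 0.2, 0.5), (1000, -0.2, 0.5)], ids=["zz", "aa"])
    assert st.select_representative(table).iloc[0]["image_id"] == "aa"


def test_representative_standardized_variant_runs():
    table = _triple_table(
        [(1000, 0.0, 0.5), (1200, 0.1, 0.6), (5000, 0.4, -0.2), (1100, 0.0, 0.55)]
    )
    out = st.select_representative(table, standardize=True)
    assert len(out) == 1 and out.iloc[0]["image_id"] in set(table["image_id"])
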
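"""Repeated-measures ANOVA, post-hocs, SP-index, FA rules, regression."""

import numpy as np
import pandas as pd
import pytest

from cadenza.stats import (
    RepeatedMeasuresAnova,
    movement_cost,
    multiple_regression,
    paired_t_bonferroni,
    rm_anova_2x2,
    rm_anova_2x2x2,
    sp_index,
    tract_mean_fa,
)

# hand-worked 4-subject 2x2 fixture (cells a1b1, a1b2, a2b1, a2b2);
# expected F values computed by hand from the sums-of-squares arithmetic
# before the implementation: F_A = 225, F_B = 507/19, F_AB = 9
_HAND_CELLS = {
    1: (10, 12, 13, 17),
    2: (11, 13, 14, 16),
    3: (9, 11, 12, 16),
    4: (10, 14, 13, 19),
}


def _hand_table(offset=0.0):
    rows = []
    for sid, (y11, y12, y21, y22) in _HAND_CELLS.items():
        for (a, b), y in zip(
            [("a1", "b1"), ("a1", "b2"), ("a2", "b1"), ("a2", "b2")],
            (y11, y12, y21, y22),
        ):
            rows.append({"subject_id": sid, "A": a, "B": b, "y": y + offset})
    return pd.DataFrame(rows)


def test_2x2_anova_matches_hand_worked_sums_of_squares():
    res = rm_anova_2x2(_hand_table(), dv="y", factors=("A", "B"))
    assert res.effect("A")["F"] == pytest.approx(225.0, abs=1e-9)
    assert res.effect("A")["partial_eta_sq"] == pytest.approx(225 / 228, abs=1e-9)
    assert res.effect("B")["F"] == pytest.approx(507 / 19, abs=1e-9)
    assert res.effect("B")["partial_eta_sq"] == pytest.approx(
        (507 / 19) / (507 / 19 + 3), abs=1e-9
    )
    assert res.effect("A x B")["F"] == pytest.approx(9.0, abs=1e-9)
    assert res.effect("A x B")["partial_eta_sq"] == pytest.approx(0.75, abs=1e-9)
    assert (res.table["df_num"] == 1).all() and (res.table["df_den"] == 3).all()


def test_partial_eta_sq_identity_holds():
    res = rm_anova_2x2(_hand_table(), dv="y", factors=("A", "B"))
    for _, row in res.table.iterrows():
        assert row["partial_eta_sq"] == pytest.approx(
            row["ss_effect"] / (row["ss_effect"] + row["ss_error"]), abs=1e-9
        )


def test_anova_location_invariance():
    a = rm_anova_2x2(_hand_table(), dv="y", factors=("A", "B")).table
    b = rm_anova_2x2(_hand_table(offset=57.3), dv="y", factors=("A", "B")).table
    pd.testing.assert_frame_equal(
        a[["F", "p", "partial_eta_sq"]], b[["F", "p", "partial_eta_sq"]],
        atol=1e-9, rtol=0,
    )


def test_anova_all_equal_cells_give_zero_f():
    df = _hand_table()
    df["y"] = df["subject_id"] * 10.0  # constant within subject
    res = rm_anova_2x2(df, dv="y", factors=("A", "B"))
    assert (res.table["F"] == 0).all()


def test_anova_agrees_with_statsmodels_anovarm():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(42)
    rows = []
    for sid in range(1, 13):
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                rows.append(
                    {"subject_id": sid, "A": a, "B": b,
                     "y": rng.normal(10 + 2 * (a == "a2") + (a == "a2") * (b == "b2"))}
                )
    df = pd.DataFrame(rows)
    ours = rm_anova_2x2(df, dv="y", factors=("A", "B")).table
    ref = AnovaRM(df, depvar="y", subject="subject_id", within=["A", "B"]).fit().anova_table
    assert ours.loc["A", "F"] == pytest.approx(ref.loc["A", "F Value"], rel=1e-8)
    assert ours.loc["B", "F"] == pytest.approx(ref.loc["B", "F Value"], rel=1e-8)
    assert ours.loc["A x B", "F"] == pytest.approx(ref.loc["A:B", "F Value"], rel=1e-8)


def test_three_way_anova_matches_statsmodels_and_invariances():
    from statsmodels.stats.anova import AnovaRM

    rng = np.random.default_rng(7)
    rows = []
    for sid in range(1, 9):
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                for g in ("g1", "g2"):
                    rows.append(
                        {"subject_id": sid, "A": a, "B": b, "G": g,
                         "y": rng.normal(5 + (a == "a2") * (g == "g2"))}
                    )
    df = pd.DataFrame(rows)
    ours = rm_anova_2x2x2(df, dv="y", factors=("A", "B", "G")).table
    ref = AnovaRM(df, depvar="y", subject="subject_id",
                  within=["A", "B", "G"]).fit().anova_table
    for ref_name, our_name in [
        ("A", "A"), ("B", "B"), ("G", "G"),
        ("A:B", "A x B"), ("A:G", "A x G"), ("B:G", "B x G"),
        ("A:B:G", "A x B x G"),
    ]:
        assert ours.loc[our_name, "F"] == pytest.approx(
            ref.loc[ref_name, "F Value"], rel=1e-8
        )
    # all-equal and location invariance
    flat = df.assign(y=1.0)
    assert (rm_anova_2x2x2(flat, dv="y", factors=("A", "B", "G")).table["F"] == 0).all()
    shifted = rm_anova_2x2x2(df.assign(y=df["y"] + 3), dv="y", factors=("A", "B", "G")).table
    np.testing.assert_allclose(shifted["F"], ours["F"], atol=1e-9)


def test_anova_rejects_incomplete_table():
    df = _hand_table().iloc[:-1]
    with pytest.raises(ValueError, match="missing"):
        rm_anova_2x2(df, dv="y", factors=("A", "B"))


# ---------------------------------------------------------------------------
# post-hoc paired t with Bonferroni
# ---------------------------------------------------------------------------


def test_paired_t_identical_vectors():
    out = paired_t_bonferroni([(np.ones(5), np.ones(5))])
    assert out.loc[0, "t"] == 0.0
    assert out.loc[0, "p_raw"] == 1.0


def test_paired_t_hand_computed_three_subjects():
    # diffs (1, 2, 3): mean 2, sd 1 -> t = 2 / (1/sqrt(3)) = 2*sqrt(3)
    out = paired_t_bonferroni([(np.array([1.0, 2.0, 3.0]), np.zeros(3))])
    assert out.loc[0, "t"] == pytest.approx(2 * np.sqrt(3), abs=1e-9)


def test_bonferroni_caps_at_one():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=6), rng.normal(size=6)
    out = paired_t_bonferroni([(a, b)], n_comparisons=50)
    assert out.loc[0, "p_bonferroni"] == min(1.0, out.loc[0, "p_raw"] * 50)
    assert out.loc[0, "p_bonferroni"] <= 1.0


# ---------------------------------------------------------------------------
# SP-index and movement cost
# ---------------------------------------------------------------------------


def _rt_table(rows):
    return pd.DataFrame(rows).set_index("subject_id")


def test_sp_index_direct_arithmetic():
    rt = _rt_table([
        {"subject_id": 1, "baseline-irregular": 900.0, "baseline-regular": 800.0,
         "structure-irregular": 850.0, "structure-regular": 820.0,
         "motor-regular": 1000.0, "motor-irregular": 1050.0},
    ])
    assert sp_index(rt).loc[1] == pytest.approx(70.0)
    # equal means -> 0; constant shift leaves SP unchanged
    flat = rt.copy()
    for c in flat.columns:
        flat[c] = 500.0
    assert sp_index(flat).loc[1] == 0.0
    assert sp_index(rt + 123.4).loc[1] == pytest.approx(70.0)


def test_movement_cost_arithmetic_and_sign():
    rt = _rt_table([
        {"subject_id": 1, "baseline-regular": 800.0, "baseline-irregular": 900.0,
         "structure-regular": 0.0, "structure-irregular": 0.0,
         "motor-regular": 950.0, "motor-irregular": 1050.0},
    ])
    assert movement_cost(rt).loc[1] == pytest.approx(150.0)
    swapped = rt.rename(columns={
        "baseline-regular": "motor-regular", "motor-regular": "baseline-regular",
        "baseline-irregular": "motor-irregular", "motor-irregular": "baseline-irregular",
    })
    assert movement_cost(swapped).loc[1] == pytest.approx(-150.0)


def test_sp_index_equals_interaction_contrast(stim_set, ic_profiles):
    from cadenza.behavior import (condition_means, filter_trials, simulate_trials,
                                  structure_cell_means)

    t = simulate_trials(stim_set, ic_profiles, n_subjects=12, seed=21)
    valid, _ = filter_trials(t)
    rt, _ = condition_means(valid)
    anova = rm_anova_2x2(structure_cell_means(rt))
    est = anova.effect("structure x context")["estimate"]
    assert sp_index(rt).mean() == pytest.approx(est, abs=1e-9)


# ---------------------------------------------------------------------------
# tract FA rules
# ---------------------------------------------------------------------------


def test_tract_fa_basic_mean():
    fa = {(0, 0, 0): 0.4, (1, 0, 0): 0.0, (2, 0, 0): 0.6}
    masks = {"ifof": [(0, 0, 0), (1, 0, 0), (2, 0, 0)]}
    freq = {v: 1.0 for v in fa}
    (res,) = tract_mean_fa(fa, masks, freq)
    assert res.mean_fa == pytest.approx(0.5)
    assert res.n_voxels == 2  # the FA=0 voxel is excluded


def test_tract_fa_overlap_and_frequency_rules():
    fa = {"a": 0.5, "b": 0.7, "c": 0.4}
    masks = {"t1": ["a", "b"], "t2": ["b", "c"]}
    freq = {"a": 1.0, "b": 1.0, "c": 0.49}
    res = {r.tract_id: r for r in tract_mean_fa(fa, masks, freq)}
    assert res["t1"].mean_fa == pytest.approx(0.5)  # shared voxel b excluded
    assert np.isnan(res["t2"].mean_fa)  # b shared, c below 50% membership
    assert res["t2"].n_voxels == 0


def test_tract_fa_rejects_out_of_range_values():
    with pytest.raises(ValueError):
        tract_mean_fa({"a": 1.4}, {"t": ["a"]}, {"a": 1.0})


# ---------------------------------------------------------------------------
# multiple regression
# ---------------------------------------------------------------------------


def test_regression_hand_worked_bivariate():
    # x = 1..5, y = (2,4,5,4,5): beta_std = r = 6/sqrt(60), t = sqrt(4.5)
    x = np.array([1.0, 2, 3, 4, 5])
    y = np.array([2.0, 4, 5, 4, 5])
    res = multiple_regression(y, x[:, None], names=["x"])
    assert res.standardized_betas[0] == pytest.approx(6 / np.sqrt(60), abs=1e-9)
    assert res.t_values[0] == pytest.approx(np.sqrt(4.5), abs=1e-9)
    assert res.adjusted_r_squared == pytest.approx(1 - 0.4 * 4 / 3, abs=1e-9)


def test_regression_noiseless_limit():
    rng = np.random.default_rng(3)
    x1 = rng.normal(size=30)
    x2 = rng.normal(size=30)
    x2 -= x2 @ x1 / (x1 @ x1) * x1  # orthogonal noise predictor
    y = 3.0 * x1
    res = multiple_regression(y, np.column_stack([x1, x2]))
    assert res.standardized_betas[0] == pytest.approx(1.0, abs=1e-9)
    assert res.standardized_betas[1] == pytest.approx(0.0, abs=1e-9)
    assert res.adjusted_r_squared == pytest.approx(1.0, abs=1e-9)


def test_regression_null_calibration():
    """Independent y: adjusted R^2 centers on 0 and the coefficient test
    rejects at roughly the nominal rate."""
    rng = np.random.default_rng(11)
    n_sims, n = 400, 50
    rejections, adj = 0, []
    for _ in range(n_sims):
        y = rng.normal(size=n)
        X = rng.normal(size=(n, 2))
        res = multiple_regression(y, X)
        rejections += res.p_values[0] < 0.05
        adj.append(res.adjusted_r_squared)
    assert abs(rejections / n_sims - 0.05) < 0.03
    assert abs(float(np.mean(adj))) < 0.02


def test_regression_recovers_planted_standardized_beta():
    rng = np.random.default_rng(5)
    betas = []
    for _ in range(300):
        fa = rng.normal(size=21)
        z = (fa - fa.mean()) / fa.std(ddof=1)
        y = 0.6 * z + np.sqrt(1 - 0.36) * rng.normal(size=21)
        res = multiple_regression(y, fa[:, None])
        betas.append(res.standardized_betas[0])
    assert float(np.mean(betas)) == pytest.approx(0.6, abs=0.05)


def test_regression_rejects_degenerate_designs():
    y = np.arange(5.0)
    with pytest.raises(ValueError, match="rank"):
        multiple_regression(y, np.column_stack([np.arange(5.0), 2 * np.arange(5.0)]))
    with pytest.raises(ValueError, match="n > p"):
        multiple_regression(np.arange(3.0), np.eye(3)[:, :2])
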
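"""SMEL, pairwise regressions, slope-interval comparison, outlier rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtorus.scoring import score_table, score_vs
from mirtorus.smel import (
    ExpressionRecord,
    compare_slopes,
    disease_discrimination,
    fc_outlier_mask,
    filter_fc_outliers,
    pairwise_regression,
    regress_axes,
    smel,
    smel_table,
)

from oracles import closed_form_ols


# --- SMEL -------------------------------------------------------------------

def test_smel_is_elementwise_scaling():
    sv = score_vs("AA")
    np.testing.assert_allclose(smel(sv, 0.0).values, 0.0)
    np.testing.assert_allclose(smel(sv, 3.0).values, 2 * smel(sv, 1.5).values)
    np.testing.assert_allclose(
        smel(sv, 1.5).values, 1.5 * np.sqrt(2) * np.array([0.417, 0.514, 0.228])
    )


def test_smel_rejects_non_finite():
    with pytest.raises(ValueError):
        smel(score_vs("AA"), float("nan"))


def test_expression_record_completes_missing_value():
    assert ExpressionRecord("m", "AD", fc=2.0).log2fc == pytest.approx(1.0)
    assert ExpressionRecord("m", "AD", log2fc=1.0).fc == pytest.approx(2.0)
    with pytest.raises(ValueError):
        ExpressionRecord("m", "AD")
    with pytest.raises(ValueError):
        ExpressionRecord("m", "AD", fc=-1.0)


def test_smel_table_joins_scores_and_expression():
    scores = score_table([("m1", "GCAU"), ("m2", "AUGC")], "VS")
    recs = [
        ExpressionRecord("m1", "AD", log2fc=2.0),
        ExpressionRecord("m2", "AD", log2fc=-1.0),
        ExpressionRecord("m9", "AD", log2fc=1.0),  # unscored, dropped
    ]
    table = smel_table(scores, recs, "log2fc")
    assert len(table) == 2
    np.testing.assert_allclose(
        table.loc[table["id"] == "m1", ["v1", "v2", "v3"]].to_numpy()[0],
        2.0 * score_vs("GCAU").values,
    )


# --- regressions ------------------------------------------------------------

def test_exact_proportionality_through_origin():
    pts = [(t, 2.0 * t) for t in range(1, 11)]
    r = pairwise_regression(pts, through_origin=True)
    assert (r.slope, r.stderr, r.r2) == (2.0, 0.0, 1.0)


def test_negative_slope_gives_negative_signed_fit():
    pts = [(t, -t) for t in range(1, 11)]
    r = pairwise_regression(pts, through_origin=True)
    assert r.slope == pytest.approx(-1.0)
    assert r.signed_fit == pytest.approx(-1.0)


@pytest.mark.parametrize("through_origin", [False, True])
def test_regression_matches_closed_form_oracle(rng, through_origin):
    a = rng.normal(size=20)
    b = 1.7 * a + rng.normal(scale=0.5, size=20)
    r = pairwise_regression(np.stack([a, b], axis=1), through_origin=through_origin)
    slope, se, p, r2 = closed_form_ols(a, b, through_origin=through_origin)
    assert r.slope == pytest.approx(slope, rel=1e-10)
    assert r.stderr == pytest.approx(se, rel=1e-10)
    assert r.pvalue == pytest.approx(p, rel=1e-8)
    assert r.r2 == pytest.approx(r2, rel=1e-10)


def test_regression_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        pairwise_regression([(1, 2), (2, 3)])
    with pytest.raises(ValueError):
        pairwise_regression([(1, 2), (1, 3), (1, 4)])  # zero-variance predictor
    with pytest.raises(ValueError):
        pairwise_regression([(0, 2), (0, 3), (0, 4)], through_origin=True)


def test_regress_axes_marks_zero_axis_na():
    vals = np.column_stack([np.arange(1.0, 11), np.arange(1.0, 11) * 2, np.zeros(10)])
    fits = regress_axes(vals, through_origin=True)
    assert fits["x-y"] is not None
    assert fits["y-z"] is None and fits["z-x"] is None


# --- slope comparison -------------------------------------------------------

def _fit(slope, se, pair="x-y"):
    from mirtorus.smel import RegressionResult

    return RegressionResult(pair, slope, se, 0.0, 1.0, np.sign(slope), 10, True)


def test_identical_fits_never_differ():
    r = _fit(1.0, 0.1)
    for k in (1, 2, 3):
        assert compare_slopes(r, r, k) is False


def test_disjoint_intervals_differ():
    assert compare_slopes(_fit(1.0, 0.01), _fit(2.0, 0.01), 2) is True


def test_axis_pair_mismatch_rejected():
    with pytest.raises(ValueError):
        compare_slopes(_fit(1.0, 0.1, "x-y"), _fit(1.0, 0.1, "y-z"), 2)


@settings(deadline=None)
@given(
    st.floats(-5, 5), st.floats(0.001, 1), st.floats(-5, 5), st.floats(0.001, 1)
)
def test_significance_monotone_in_k(s1, e1, s2, e2):
    r1, r2 = _fit(s1, e1), _fit(s2, e2)
    sig = [compare_slopes(r1, r2, k) for k in (1, 2, 3)]
    assert sig[0] >= sig[1] >= sig[2]  # wider intervals can only overlap more


# --- disease discrimination -------------------------------------------------

def _line_panel(slope, n=30, noise=0.001, seed=0):
    rng = np.random.default_rng(seed)
    t = np.linspace(1, 5, n)
    v1 = t
    v2 = slope * t + rng.normal(scale=noise, size=n)
    v3 = 0.5 * slope * t + rng.normal(scale=noise, size=n)
    return np.column_stack([v1, v2, v3])


def test_well_separated_slopes_all_significant():
    panels = {"D1": _line_panel(1.0, seed=1), "D2": _line_panel(2.0, seed=2)}
    result = disease_discrimination(panels, 2)
    assert result.marks["x-y"] == "O"


def test_duplicated_disease_never_discriminates():
    panel = _line_panel(1.0, seed=3)
    panels = {"D1": panel, "D2": panel.copy()}
    for k in (1, 2, 3):
        assert set(disease_discrimination(panels, k).marks.values()) == {"x"}


def test_structure_a_field_axes_report_na():
    base = _line_panel(1.5, seed=4)
    base[:, 2] = 0.0  # planar structure: no z component anywhere
    panels = {"D1": base, "D2": 2.0 * base}
    marks = disease_discrimination(panels, 2).marks
    assert marks["y-z"] == "NA" and marks["z-x"] == "NA"
    assert marks["x-y"] in ("O", "x")


def test_discrimination_requires_two_diseases():
    with pytest.raises(ValueError):
        disease_discrimination({"D1": _line_panel(1.0)}, 2)


def test_single_scoring_slope_recovered_when_expression_constant():
    # all x equal: the scalar cancels, the SMEL slope equals the score slope
    scores = _line_panel(1.3, noise=0.0)
    x = 2.7
    fit_scores = regress_axes(scores, through_origin=True)["x-y"]
    fit_smel = regress_axes(scores * x, through_origin=True)["x-y"]
    assert fit_smel.slope == pytest.approx(fit_scores.slope, rel=1e-12)


# --- outlier rule -----------------------------------------------------------

@pytest.mark.parametrize(
    "values, kept, removed",
    [
        ([1000, 10, 9, 8], [10, 9, 8], [1000]),
        ([4, 3, 2], [4, 3, 2], []),
        ([100, 40, 3, 2], [3, 2], [100, 40]),
    ],
)
def test_outlier_rule_fixtures(values, kept, removed):
    got_kept, got_removed = filter_fc_outliers(values)
    assert got_kept.tolist() == kept
    assert got_removed.tolist() == removed


def test_outlier_first_mode_removes_at_most_largest():
    kept, removed = filter_fc_outliers([100, 40, 3, 2], mode="first")
    assert removed.tolist() == [100]
    assert kept.tolist() == [40, 3, 2]


def test_outlier_mask_preserves_input_order():
    mask = fc_outlier_mask([8, 1000, 9, 10])
    assert mask.tolist() == [True, False, True, True]


def test_outlier_rule_rejects_nonpositive():
    with pytest.raises(ValueError):
        filter_fc_outliers([10, 0, 5])


@settings(deadline=None, max_examples=200)
@given(st.lists(st.floats(0.01, 1e6), min_size=1, max_size=30))
def test_outlier_filter_is_idempotent(values):
    kept, _ = filter_fc_outliers(values)
    if len(kept):
        kept2, removed2 = filter_fc_outliers(kept)
        assert removed2.size == 0
        assert kept2.tolist() == kept.tolist()
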
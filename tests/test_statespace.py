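"""Unit and property tests for scale transforms and the 2x2 decomposition."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings
from hypothesis import strategies as st

from ssea import (
    CellMeans,
    FactorialDataset,
    MissingCellError,
    ScaleSpec,
    SSEAError,
    StateSpacePoint,
    cell_means,
    classify_response,
    decompose,
    enumerate_2x2_groups,
    statespace_table,
    transform_scale,
)
from ssea.statespace import Group2x2

from conftest import make_2x2_dataset

finite = st.floats(min_value=-50, max_value=50, allow_nan=False)


# ---------------------------------------------------------------- transforms
@pytest.mark.parametrize(
    "name, values, expected",
    [
        ("raw", [0.3, 0.9], [0.3, 0.9]),
        ("log", [1.0], [0.0]),
        ("logit", [0.5], [0.0]),
    ],
)
def test_transform_scale_fixed_points(name, values, expected):
    spec = ScaleSpec(name, zero_one_adjustment=0.0)
    np.testing.assert_allclose(transform_scale(values, spec), expected)


def test_transform_is_strictly_monotone():
    x = np.linspace(0.05, 0.95, 20)
    for name in ("raw", "log", "logit"):
        y = transform_scale(x, ScaleSpec(name, 0.0))
        assert np.all(np.diff(y) > 0)


def test_transform_continuity_adjustment_uses_trial_counts():
    # (x*n + 0.5) / (n + 1) with n = 10: 0 -> 0.5/11, 1 -> 10.5/11
    spec = ScaleSpec("logit", zero_one_adjustment=0.5)
    got = transform_scale([0.0, 1.0], spec, n_trials=[10, 10])
    p = np.array([0.5 / 11, 10.5 / 11])
    np.testing.assert_allclose(got, np.log(p / (1 - p)))


def test_transform_domain_violation_names_value_and_row():
    with pytest.raises(SSEAError, match=r"0\.0.*row 1"):
        transform_scale([0.5, 0.0], ScaleSpec("log", 0.0))
    with pytest.raises(SSEAError, match="logit"):
        transform_scale([1.0], ScaleSpec("logit", 0.5))  # no trials -> strict


# ---------------------------------------------------------------- cell means
def test_cell_means_and_se_hand_computed():
    data = make_2x2_dataset(
        {
            ("0", "0"): [0.2, 0.4],
            ("a", "0"): [0.8, 0.8, 0.8],
            ("0", "b"): [0.5, 0.7],
            ("a", "b"): [0.1, 0.3],
        }
    )
    grp = Group2x2(("0", "0"), ("a", "b"))
    m = cell_means(data, grp, ScaleSpec("raw"))
    assert m.r00 == pytest.approx(0.3)
    assert m.se00 == pytest.approx(0.1)
    assert m.r10 == pytest.approx(0.8)
    assert m.se10 == pytest.approx(0.0, abs=1e-12)
    assert (m.n00, m.n10, m.n01, m.n11) == (2, 3, 2, 2)


def test_cell_means_single_replicate_warns_and_has_zero_se():
    data = make_2x2_dataset({c: [float(i)] for i, c in enumerate(
        [("0", "0"), ("a", "0"), ("0", "b"), ("a", "b")])})
    grp = Group2x2(("0", "0"), ("a", "b"))
    with pytest.warns(UserWarning, match="single replicate"):
        m = cell_means(data, grp, ScaleSpec("raw"))
    assert (m.r00, m.r10, m.r01, m.r11) == (0.0, 1.0, 2.0, 3.0)
    assert m.se11 == 0.0


def test_cell_means_missing_cell_error_names_cell():
    data = make_2x2_dataset(
        {("0", "0"): [1.0], ("a", "0"): [1.0], ("0", "b"): [1.0]}
    )
    grp = Group2x2(("0", "0"), ("a", "b"))
    with pytest.raises(MissingCellError, match="'a'.*'b'"):
        with pytest.warns(UserWarning):
            cell_means(data, grp, ScaleSpec("raw"))


# --------------------------------------------------------------- decompose
@pytest.mark.parametrize(
    "means, expected",
    [
        ((5.0, 5.0, 5.0, 5.0), (0.0, 0.0, 0.0)),
        ((1.0, 2.0, 3.0, 4.0), (1.0, 2.0, 0.0)),
        ((0.9, 0.8, 0.7, 0.3), (-0.1, -0.2, -0.3)),
    ],
)
def test_decompose_examples(means, expected):
    p = decompose(CellMeans(*means))
    assert (p.f1, p.f2, p.g) == pytest.approx(expected)
    assert p.additive == p.f1 + p.f2


def test_g_equals_four_times_sum_coded_interaction_coefficient(rng):
    """Oracle: saturated two-way OLS with sum-to-zero coding on replicated data."""
    for _ in range(5):
        mus = rng.normal(0, 2, size=4)
        data = make_2x2_dataset(
            {
                ("0", "0"): list(mus[0] + rng.normal(0, 0.2, 4)),
                ("a", "0"): list(mus[1] + rng.normal(0, 0.2, 4)),
                ("0", "b"): list(mus[2] + rng.normal(0, 0.2, 4)),
                ("a", "b"): list(mus[3] + rng.normal(0, 0.2, 4)),
            }
        )
        grp = Group2x2(("0", "0"), ("a", "b"))
        p = decompose(cell_means(data, grp, ScaleSpec("raw")))
        fit = smf.ols(
            "response ~ C(driver1, Sum) * C(driver2, Sum)", data=data.df
        ).fit()
        coef = fit.params["C(driver1, Sum)[S.0]:C(driver2, Sum)[S.0]"]
        assert p.g == pytest.approx(4.0 * coef)


@settings(deadline=None, max_examples=60)
@given(r00=finite, r10=finite, r01=finite, r11=finite, c=finite)
def test_decompose_identities_and_translation_invariance(r00, r10, r01, r11, c):
    p = decompose(CellMeans(r00, r10, r01, r11))
    # exact interaction-contrast identity
    assert p.g == pytest.approx(r11 - r10 - r01 + r00, abs=1e-9)
    assert p.additive == p.f1 + p.f2
    shifted = decompose(CellMeans(r00 + c, r10 + c, r01 + c, r11 + c))
    assert (shifted.f1, shifted.f2, shifted.g) == pytest.approx(
        (p.f1, p.f2, p.g), abs=1e-9
    )
    assert shifted.r00 == pytest.approx(p.r00 + c)
    # swapping driver roles swaps f1/f2 and leaves g unchanged
    swapped = decompose(CellMeans(r00, r01, r10, r11))
    assert (swapped.f1, swapped.f2) == (p.f2, p.f1)
    assert swapped.g == p.g


def test_multiplicative_effects_are_additive_on_log_scale_only():
    # cell means R(a,b) = R0 * ma * mb: exactly multiplicative, noiseless
    r0, ma, mb = 0.9, 0.7, 0.5
    cells = {
        ("0", "0"): [r0] * 2,
        ("a", "0"): [r0 * ma] * 2,
        ("0", "b"): [r0 * mb] * 2,
        ("a", "b"): [r0 * ma * mb] * 2,
    }
    data = make_2x2_dataset(cells)
    grp = Group2x2(("0", "0"), ("a", "b"))
    g_log = decompose(cell_means(data, grp, ScaleSpec("log", 0.0))).g
    g_raw = decompose(cell_means(data, grp, ScaleSpec("raw"))).g
    assert g_log == pytest.approx(0.0, abs=1e-12)
    assert abs(g_raw) > 1e-3


# ------------------------------------------------------------ group listing
@pytest.mark.parametrize("m, n", [(2, 2), (3, 3), (4, 2), (2, 5), (3, 4)])
def test_enumerate_groups_matches_brute_force(m, n):
    d1 = [f"a{i}" for i in range(m)]
    d2 = [f"b{j}" for j in range(n)]
    groups = enumerate_2x2_groups(d1, d2)
    brute = [
        (a, b)
        for a in d1 for b in d2
        if a != d1[0] and b != d2[0]
    ]
    assert len(groups) == (m - 1) * (n - 1)
    assert [g.levels for g in groups] == brute  # driver1-major order
    assert all(g.reference == (d1[0], d2[0]) for g in groups)
    assert all(g.reference in g.cells for g in groups)


def test_enumerate_groups_reference_override_and_errors():
    groups = enumerate_2x2_groups(["a", "b", "c"], ["x", "y"], reference=("b", "y"))
    assert [g.levels for g in groups] == [("a", "x"), ("c", "x")]
    with pytest.raises(SSEAError, match="reference"):
        enumerate_2x2_groups(["a", "b"], ["x", "y"], reference=("z", "x"))
    with pytest.raises(SSEAError, match="two levels"):
        enumerate_2x2_groups(["a"], ["x", "y"])


# ----------------------------------------------------------- classification
def _point(f1, f2, g, se_g=0.01):
    return StateSpacePoint(f1=f1, f2=f2, g=g, additive=f1 + f2, r00=0.0, se_g=se_g)


@pytest.mark.parametrize(
    "f1, f2, g, label",
    [
        (0.5, 0.5, 0.4, "synergistic"),     # double positive, amplified
        (0.5, 0.5, -0.4, "antagonistic"),   # double positive, dampened
        (-0.5, -0.5, -0.4, "synergistic"),  # double negative, amplified harm
        (-0.5, -0.5, 0.4, "antagonistic"),  # double negative, mitigated
        (0.5, -0.2, 0.4, "synergistic"),    # opposite signs, |combined|>|additive|
        (0.5, -0.2, -0.2, "antagonistic"),  # opposite signs, falls short
        (0.0, 0.5, 0.4, "indeterminate"),   # needed single-effect sign is 0
    ],
)
def test_classify_directions(f1, f2, g, label):
    assert classify_response(_point(f1, f2, g)).label == label


def test_classify_additive_when_interval_spans_zero():
    cls = classify_response(_point(1.0, -2.0, 0.05, se_g=0.1))
    assert cls.label == "additive"
    assert cls.decision_basis == "interval"
    # exact zero g is additive regardless of uncertainty
    assert classify_response(_point(1.0, 1.0, 0.0, se_g=0.0)).label == "additive"


def test_classify_with_external_p_value_overrides_interval():
    p = _point(0.5, 0.5, 0.4, se_g=1e9)  # interval would say additive
    assert classify_response(p, p_value=0.01).label == "synergistic"
    assert classify_response(p, p_value=0.50).label == "additive"
    assert classify_response(p, p_value=0.01).decision_basis == "test"


def test_classify_opposite_sign_basis_is_flagged():
    cls = classify_response(_point(0.5, -0.2, 0.4))
    assert "opposite-sign" in cls.decision_basis


# ------------------------------------------------------------- batch driver
def test_statespace_table_point_counts():
    # 13 units x 2x2 -> 13 points
    rows = []
    for u in range(13):
        for d1 in ("0", "a"):
            for d2 in ("0", "b"):
                rows.append(
                    {"unit": f"G{u}", "context": "", "driver1": d1,
                     "driver2": d2, "replicate": "R1",
                     "response": float(u + (d1 == "a") + 2 * (d2 == "b"))}
                )
    data = FactorialDataset(pd.DataFrame(rows))
    with pytest.warns(UserWarning):
        pts = statespace_table(data)
    assert len(pts) == 13
    assert [p.unit_id for p in pts] == [f"G{u}" for u in range(13)]

    # 1 unit, 3x3 -> (m-1)(n-1) = 4 points
    rows = [
        {"unit": "u", "context": "", "driver1": d1, "driver2": d2,
         "replicate": "R1", "response": 0.0}
        for d1 in "abc" for d2 in "xyz"
    ]
    with pytest.warns(UserWarning):
        pts = statespace_table(FactorialDataset(pd.DataFrame(rows)))
    assert len(pts) == 4

    # empty dataset -> empty list
    empty = FactorialDataset(
        pd.DataFrame(columns=["unit", "context", "driver1", "driver2",
                              "replicate", "response"])
    )
    assert statespace_table(empty) == []
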
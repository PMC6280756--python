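import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_expression
from drre_kit.expression import (call_de, classify_profile, coregulation,
                                 de_sets)

EPS = 0.01


def test_call_de_boundaries():
    expr = make_expression({
        "up_exact":   {("control", "early"): 1.0, ("regeneration", "early"): 1.7 * 1.01 - EPS},
        "up_clear":   {("control", "early"): 1.0, ("regeneration", "early"): 2.0},
        "down_clear": {("control", "early"): 2.0, ("regeneration", "early"): 1.0},
        "flat":       {("control", "early"): 1.0, ("regeneration", "early"): 1.0},
        "just_under": {("control", "early"): 1.0, ("regeneration", "early"): 1.699},
    })
    calls = call_de(expr, "early").set_index("gene_id")
    assert calls.loc["up_exact", "direction"] == "up"  # ratio == theta counts
    assert calls.loc["up_clear", "direction"] == "up"
    assert calls.loc["down_clear", "direction"] == "down"
    assert calls.loc["flat", "direction"] == "nde"
    assert calls.loc["just_under", "direction"] == "nde"


def test_call_de_zero_control_uses_pseudocount():
    expr = make_expression({
        "g": {("control", "early"): 0.0, ("regeneration", "early"): 1.0},
    })
    calls = call_de(expr, "early").set_index("gene_id")
    assert calls.loc["g", "fold_change"] == pytest.approx((1.0 + EPS) / EPS)
    assert calls.loc["g", "direction"] == "up"


def test_call_de_swap_symmetry():
    """Swapping conditions flips up and down."""
    rows = {f"g{i}": {("control", "early"): c, ("regeneration", "early"): r}
            for i, (c, r) in enumerate([(1, 3), (3, 1), (2, 2), (0.5, 5)])}
    fwd = call_de(make_expression(rows), "early").set_index("gene_id")
    swapped = {
        g: {("control", "early"): v[("regeneration", "early")],
            ("regeneration", "early"): v[("control", "early")]}
        for g, v in rows.items()
    }
    rev = call_de(make_expression(swapped), "early").set_index("gene_id")
    flip = {"up": "down", "down": "up", "nde": "nde"}
    for g in rows:
        assert rev.loc[g, "direction"] == flip[fwd.loc[g, "direction"]]


@given(st.floats(0, 100), st.floats(0, 100))
def test_call_de_direction_consistent_with_fold(c, r):
    expr = make_expression({
        "g": {("control", "early"): c, ("regeneration", "early"): r}})
    row = call_de(expr, "early").set_index("gene_id").loc["g"]
    fold = (r + EPS) / (c + EPS)
    if fold >= 1.7:
        assert row.direction == "up"
    elif 1 / fold >= 1.7:
        assert row.direction == "down"
    else:
        assert row.direction == "nde"


def test_de_sets_partition():
    expr = make_expression({
        "a": {("control", "early"): 1.0, ("regeneration", "early"): 5.0},
        "b": {("control", "early"): 5.0, ("regeneration", "early"): 1.0},
        "c": {},
    })
    sets = de_sets(call_de(expr, "early"))
    assert sets["up"] == {"a"} and sets["down"] == {"b"}


def test_classify_profile_boundaries():
    assert classify_profile([40, 40, 40]) == "high"          # > 30
    assert classify_profile([30, 30, 30]) == "moderate"      # (5, 30]
    assert classify_profile([5, 5, 5]) == "low"              # (1, 5]
    assert classify_profile([1, 1, 1]) == "silenced"         # <= 1
    assert classify_profile([0, 0, 0]) == "silenced"
    # (max+eps)/(min+eps) > 2 -> variable, takes precedence
    assert classify_profile([10, 10, 25]) == "variable"
    assert classify_profile([10, 10, 20]) == "moderate"      # ratio < 2


def test_classify_profile_needs_three_values():
    with pytest.raises(ValueError):
        classify_profile([1, 2])


def test_coregulation_log_pearson():
    a = [1.0, 2.0, 4.0]
    b = [3.0, 6.0, 12.0]  # proportional -> log-shifted, r ~ 1
    assert coregulation(a, b) == pytest.approx(1.0, abs=1e-6)
    la = np.log(np.array(a) + EPS)
    lb = np.log(np.array([5.0, 1.0, 2.0]) + EPS)
    expected = np.corrcoef(la, lb)[0, 1]
    assert coregulation(a, [5.0, 1.0, 2.0]) == pytest.approx(expected)


def test_coregulation_degenerate_is_nan():
    assert math.isnan(coregulation([1, 1, 1], [1, 2, 3]))
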
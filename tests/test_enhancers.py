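import math

import pandas as pd
import pytest

from drre_kit.enhancers import (activity_call, ddct_fold_enrichment,
                                feature_status)
from drre_kit.intervals import GenomicInterval, RegionSet
from drre_kit.signal import SignalTrack


def _iv(s, e):
    return GenomicInterval("chr1", s, e)


def test_feature_marked_within_window():
    drre = _iv(10_000, 10_400)
    assert feature_status(drre, RegionSet([_iv(9_400, 9_600)])) == "marked"
    assert feature_status(drre, RegionSet([_iv(10_800, 11_000)])) == "marked"
    # expanded interval is [9_500, 10_900); book-ended peaks share no base
    assert feature_status(drre, RegionSet([_iv(9_300, 9_501)])) == "marked"
    assert feature_status(drre, RegionSet([_iv(9_300, 9_500)])) == "not_marked"
    assert feature_status(drre, RegionSet([_iv(10_899, 11_000)])) == "marked"
    assert feature_status(drre, RegionSet([_iv(10_900, 11_000)])) == "not_marked"


def test_higher_signal_requires_strictly_greater_mean():
    drre = _iv(0, 100)
    no_peaks = RegionSet()
    reg = SignalTrack.from_records([("chr1", 0, 100, 5.0)])
    ctl_lo = SignalTrack.from_records([("chr1", 0, 100, 4.0)])
    ctl_eq = SignalTrack.from_records([("chr1", 0, 100, 5.0)])
    assert feature_status(drre, no_peaks, reg, ctl_lo) == "higher_signal"
    assert feature_status(drre, no_peaks, reg, ctl_eq) == "not_marked"


def test_marked_takes_precedence_over_signal():
    drre = _iv(0, 100)
    peaks = RegionSet([_iv(0, 100)])
    reg = SignalTrack.from_records([("chr1", 0, 100, 9.0)])
    ctl = SignalTrack.from_records([("chr1", 0, 100, 1.0)])
    assert feature_status(drre, peaks, reg, ctl) == "marked"


def test_activity_call_any_feature():
    present = activity_call({"H3K4me1": "marked", "H3K27ac": "not_marked",
                             "PolII": "not_marked"})
    assert present.activity == "presence"
    assert present.n_features_present == 1
    via_signal = activity_call({"H3K4me1": "not_marked",
                                "H3K27ac": "higher_signal",
                                "PolII": "not_marked"})
    assert via_signal.activity == "presence"
    absent = activity_call({f: "not_marked"
                            for f in ("H3K4me1", "H3K27ac", "PolII")})
    assert absent.activity == "absence"


def qpcr_table(ct_rows):
    return pd.DataFrame(ct_rows,
                        columns=["region_id", "condition", "role",
                                 "replicate", "ct"])


def test_ddct_hand_worked_example():
    # regeneration: target (25, 24), reference (20, 20) -> dCt = 4.5
    # control: target (25, 25), reference (19.5, 19.5)  -> dCt = 5.5
    # ddCt = -1 -> fold = 2
    rows = [
        ("r1", "regeneration", "target", 1, 25.0),
        ("r1", "regeneration", "target", 2, 24.0),
        ("r1", "regeneration", "reference", 1, 20.0),
        ("r1", "regeneration", "reference", 2, 20.0),
        ("r1", "control", "target", 1, 25.0),
        ("r1", "control", "target", 2, 25.0),
        ("r1", "control", "reference", 1, 19.5),
        ("r1", "control", "reference", 2, 19.5),
    ]
    res = ddct_fold_enrichment(qpcr_table(rows), "r1")
    assert res["ddct"] == pytest.approx(-1.0)
    assert res["fold"] == pytest.approx(2.0)
    # delta-method SEM: var of each Ct mean, only target/regeneration varies
    var_sum = 0.5 / 2  # s^2/n for (25, 24): sample variance 0.5, n = 2
    assert res["sem"] == pytest.approx(2.0 * math.log(2) * math.sqrt(var_sum))


def test_ddct_identity_when_conditions_match():
    rows = [
        ("r1", cond, role, rep, ct)
        for cond in ("control", "regeneration")
        for role, ct in (("target", 24.0), ("reference", 20.0))
        for rep in (1, 2)
    ]
    res = ddct_fold_enrichment(qpcr_table(rows), "r1")
    assert res["fold"] == pytest.approx(1.0)
    assert res["sem"] == pytest.approx(0.0)


def test_ddct_shift_invariance():
    """Adding a constant to every Ct leaves the fold unchanged."""
    rows = [
        ("r1", "regeneration", "target", 1, 23.0),
        ("r1", "regeneration", "reference", 1, 20.0),
        ("r1", "control", "target", 1, 25.0),
        ("r1", "control", "reference", 1, 20.0),
    ]
    base = ddct_fold_enrichment(qpcr_table(rows), "r1")
    shifted = qpcr_table([(r, c, o, rep, ct + 3.0)
                          for r, c, o, rep, ct in rows])
    assert ddct_fold_enrichment(shifted, "r1")["fold"] == \
        pytest.approx(base["fold"])
    assert base["fold"] == pytest.approx(4.0)  # ddCt = 3 - 5 = -2


def test_ddct_missing_region_raises():
    rows = [("r1", "control", "target", 1, 20.0)]
    with pytest.raises(ValueError):
        ddct_fold_enrichment(qpcr_table(rows), "r2")
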
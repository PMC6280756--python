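import pytest

from drre_kit.conservation import (ReferenceSet, anchor_profile, classify_usage,
                                   species_conservation)
from drre_kit.intervals import GenomicInterval, RegionSet
from drre_kit.signal import SignalTrack


def _iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


def refset(label, regions, stage="embryo", tissue="whole"):
    return ReferenceSet(label, stage, tissue, RegionSet(regions))


def test_reused_requires_one_overlap():
    drre = _iv(1000, 1400)
    refs = [refset("r1", [_iv(5000, 5400)]),
            refset("r2", [_iv(1300, 1700)])]
    call = classify_usage(drre, refs, "d1")
    assert call.usage == "reused"
    assert call.supporting_datasets == ("r2",)


def test_novel_when_no_overlap():
    drre = _iv(1000, 1400)
    call = classify_usage(drre, [refset("r1", [_iv(5000, 5400)])])
    assert call.usage == "novel" and call.supporting_datasets == ()


def test_usage_monotone_in_references():
    """Adding reference sets can only turn novel into reused."""
    drre = _iv(1000, 1400)
    refs = [refset("r1", [_iv(9000, 9400)])]
    assert classify_usage(drre, refs).usage == "novel"
    refs.append(refset("r2", [_iv(900, 1100)]))
    assert classify_usage(drre, refs).usage == "reused"


def test_rejects_assayed_condition_reference():
    drre = _iv(0, 100)
    bad = refset("bad", [_iv(0, 100)], stage="L3", tissue="wing")
    with pytest.raises(ValueError):
        classify_usage(drre, [bad])


def test_rejects_duplicate_labels():
    drre = _iv(0, 100)
    refs = [refset("r", [_iv(0, 50)]), refset("r", [_iv(60, 90)])]
    with pytest.raises(ValueError):
        classify_usage(drre, refs)


def test_anchor_profile_shape_and_values():
    track = SignalTrack.from_records([("chr1", 900, 1100, 4.0)])
    prof = anchor_profile([("chr1", 1000)], track, flank=500)
    assert list(prof.columns) == ["offset", "mean", "n"]
    assert len(prof) == 1001
    assert prof.offset.iloc[0] == -500 and prof.offset.iloc[-1] == 500
    at = prof.set_index("offset")["mean"]
    assert at[0] == 4.0 and at[-100] == 4.0 and at[99] == 4.0
    assert at[100] == 0.0 and at[-101] == 0.0


def test_anchor_profile_averages_anchors():
    track = SignalTrack.from_records([("chr1", 0, 2000, 2.0),
                                      ("chr1", 5000, 5001, 8.0)])
    prof = anchor_profile([("chr1", 1000), ("chr1", 5000)], track, flank=10)
    at = prof.set_index("offset")["mean"]
    assert at[0] == pytest.approx(5.0)  # (2 + 8) / 2
    assert at[1] == pytest.approx(1.0)  # (2 + 0) / 2


def test_species_conservation_tau_monotone():
    drre = _iv(0, 100)
    masks = {
        "sp_full": RegionSet([_iv(0, 100)]),
        "sp_half": RegionSet([_iv(0, 50)]),
        "sp_none": RegionSet(),
    }
    n_lo, pct = species_conservation(drre, masks, tau=0.4)
    n_hi, _ = species_conservation(drre, masks, tau=0.6)
    assert n_lo == 2 and n_hi == 1
    assert pct == pytest.approx(100 * (1.0 + 0.5 + 0.0) / 3)
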
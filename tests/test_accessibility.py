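import pytest

from drre_kit.accessibility import (Peak, classify_drre, classify_fragment,
                                    concordant_peaks, consensus_regions,
                                    differential_accessibility, region_height)
from drre_kit.intervals import GenomicInterval, RegionSet
from drre_kit.signal import SignalTrack


def _peak(start, end, height=10.0, summit=None):
    return Peak(GenomicInterval("chr1", start, end),
                (start + end) // 2 if summit is None else summit, height)


def test_fragment_length_boundaries():
    assert classify_fragment(99) == "NF"
    assert classify_fragment(100) == "other"
    assert classify_fragment(179) == "other"
    assert classify_fragment(180) == "MN"
    assert classify_fragment(247) == "MN"
    assert classify_fragment(248) == "other"
    assert classify_fragment(1) == "NF"


def test_concordant_peaks_keeps_rep1_coordinates():
    rep1 = [_peak(100, 500, 10.0), _peak(2000, 2400, 8.0)]
    rep2 = [_peak(150, 550, 14.0)]  # overlaps only the first
    kept = concordant_peaks(rep1, rep2)
    assert len(kept) == 1
    assert kept[0].interval == GenomicInterval("chr1", 100, 500)
    assert kept[0].summit == rep1[0].summit
    assert kept[0].height == pytest.approx(12.0)  # mean of own and partner


def test_concordance_is_identity_on_equal_reps():
    reps = [_peak(0, 100, 3.0), _peak(500, 700, 9.0)]
    kept = concordant_peaks(reps, reps)
    assert [(p.interval, p.height) for p in kept] == \
        [(p.interval, p.height) for p in reps]


def test_consensus_regions_merges_sets():
    regions = consensus_regions([[_peak(0, 100)], [_peak(50, 150)]])
    assert regions == [GenomicInterval("chr1", 0, 150)]


def test_region_height_is_max_per_base():
    track = SignalTrack.from_records([("chr1", 0, 50, 2.0), ("chr1", 50, 100, 7.0)])
    assert region_height(GenomicInterval("chr1", 0, 100), track) == 7.0
    assert region_height(GenomicInterval("chr1", 200, 300), track) == 0.0


def test_differential_fold_boundary():
    # stored heights; theta = 1.5 with eps 0.01
    ctl = [_peak(0, 400, 10.0)]
    at_threshold = 1.5 * 10.01 - 0.01
    reg = [_peak(0, 400, at_threshold), _peak(1000, 1400, 10.0)]
    diffs = differential_accessibility(ctl, reg, theta=1.5)
    by_start = {d.interval.start: d for d in diffs}
    assert by_start[0].mode == "height_fold"
    assert by_start[0].fold == pytest.approx(1.5)
    assert by_start[1000].mode == "presence_only"
    assert by_start[1000].fold is None
    # just under threshold is not returned
    reg_low = [_peak(0, 400, at_threshold - 0.1)]
    assert differential_accessibility(ctl, reg_low, theta=1.5) == []


def test_differential_with_tracks_uses_max_height():
    ctl = [_peak(0, 400)]
    reg = [_peak(0, 400)]
    ctl_track = SignalTrack.from_records([("chr1", 0, 400, 4.0)])
    reg_track = SignalTrack.from_records([("chr1", 0, 200, 2.0),
                                          ("chr1", 200, 400, 9.0)])
    diffs = differential_accessibility(ctl, reg, ctl_track, reg_track)
    assert len(diffs) == 1
    assert diffs[0].fold == pytest.approx(9.01 / 4.01)


def test_classify_drre_taxonomy():
    region = GenomicInterval("chr1", 100, 500)
    open_here = RegionSet([GenomicInterval("chr1", 50, 550)])
    open_elsewhere = RegionSet([GenomicInterval("chr1", 10_000, 10_400)])
    from drre_kit.accessibility import DiffRegion
    diff = DiffRegion(region, 300, "presence_only")
    # open in neither control nor L3 -> emerging
    assert classify_drre(diff, open_elsewhere, open_elsewhere) == "emerging"
    # open in L3 only still disqualifies emerging
    assert classify_drre(diff, open_elsewhere, open_here) == "increasing"
    assert classify_drre(diff, open_here, open_elsewhere) == "increasing"


def test_peak_validation():
    with pytest.raises(ValueError):
        Peak(GenomicInterval("chr1", 0, 100), 100, 1.0)  # summit out of range
    with pytest.raises(ValueError):
        Peak(GenomicInterval("chr1", 0, 100), 50, -1.0)
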
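"""Differential chromatin accessibility and the DRRE taxonomy.

Damage-responsive regulatory elements (DRREs) are regions more accessible in
regenerating tissue than in matched controls.  The calling rule is the one
used for the wing-disc ATAC-seq analysis: a regeneration peak with no
control counterpart is kept by presence/absence; one called in both
conditions is kept when its height is at least ``theta``-fold (default 1.5)
higher in regeneration.  DRREs are then *emerging* (open only after damage:
no overlap with the same-timepoint control open set nor with the untreated
L3 open set) or *increasing* (already open before damage but more
accessible after it).

Fragment-size partitioning of ATAC reads into nucleosome-free (NF, < 100 bp)
and mononucleosome (MN, 180-247 bp) classes lives here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .intervals import GenomicInterval, RegionSet, merge_intervals, overlaps
from .signal import SignalTrack

__all__ = [
    "Peak",
    "DiffRegion",
    "DRRE",
    "classify_fragment",
    "concordant_peaks",
    "consensus_regions",
    "region_height",
    "differential_accessibility",
    "classify_drre",
    "classify_drres",
]

NF_MAX_EXCL = 100     # reads shorter than 100 bp are nucleosome-free
MN_MIN, MN_MAX = 180, 247   # mononucleosome fragment bounds, inclusive


@dataclass(frozen=True)
class Peak:
    """A called peak: interval plus absolute summit position and height."""

    interval: GenomicInterval
    summit: int
    height: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside {self.interval}"
            )
        if self.height < 0:
            raise ValueError("peak height must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class DiffRegion:
    """A region more accessible in regeneration than in control."""

    interval: GenomicInterval
    summit: int
    mode: str                      # "presence_only" | "height_fold"
    fold: Optional[float] = None   # set only for height_fold
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("presence_only", "height_fold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "height_fold" and self.fold is None:
            raise ValueError("height_fold region requires a fold value")


@dataclass
class DRRE:
    """A classified DRRE; annotation/usage/activity are filled downstream."""

    region: DiffRegion
    drre_class: str                        # "emerging" | "increasing"
    prior_openness: str = ""               # provenance: which prior sets overlapped
    annotation: Optional[object] = None    # AnnotationCategory
    usage: Optional[object] = None         # UsageCall
    activity: Optional[object] = None      # ActivityCall

    @property
    def interval(self) -> GenomicInterval:
        return self.region.interval

    @property
    def summit(self) -> int:
        return self.region.summit


def classify_fragment(length: int) -> str:
    """NF / MN / other classification of an ATAC fragment length in bp."""
    if length <= 0:
        raise ValueError(f"fragment length must be positive, got {length}")
    if length < NF_MAX_EXCL:
        return "NF"
    if MN_MIN <= length <= MN_MAX:
        return "MN"
    return "other"


def _sort_by_position(peaks: Iterable[Peak]) -> Dict[str, List[Peak]]:
    per: Dict[str, List[Peak]] = {}
    for p in peaks:
        per.setdefault(p.chrom, []).append(p)
    for chrom in per:
        per[chrom].sort(key=lambda p: (p.interval.start, p.interval.end))
    return per


def _overlapping_peaks(peak: Peak, per_chrom: Dict[str, List[Peak]]) -> List[Peak]:
    hits = []
    for q in per_chrom.get(peak.chrom, ()):
        if q.interval.start >= peak.interval.end:
            break
        if overlaps(peak.interval, q.interval):
            hits.append(q)
    return hits


def concordant_peaks(rep1: Sequence[Peak], rep2: Sequence[Peak]) -> List[Peak]:
    """Peaks called in both biological replicates.

    A rep1 peak is retained iff it overlaps >= 1 rep2 peak (>= 1 bp).  The
    retained peak keeps rep1 coordinates and summit; its height becomes the
    mean of its own height and the heights of all overlapping partners.
    """
    by_chrom2 = _sort_by_position(rep2)
    out: List[Peak] = []
    for p in rep1:
        partners = _overlapping_peaks(p, by_chrom2)
        if not partners:
            continue
        height = float(np.mean([p.height] + [q.height for q in partners]))
        out.append(Peak(p.interval, p.summit, height, p.sample_id))
    return out


def consensus_regions(peak_sets: Iterable[Sequence[Peak]]) -> List[GenomicInterval]:
    """Merged union of all samples' concordant peak intervals."""
    return merge_intervals(p.interval for ps in peak_sets for p in ps)


def region_height(region: GenomicInterval, track: SignalTrack, stat: str = "max") -> float:
    """Peak height of a region from a signal track.

    ``stat='max'`` (default) is the maximum per-base signal, matching the
    summit-height reading of the calling rule; ``stat='mean'`` is available.
    """
    if stat == "max":
        return track.max_over(region)
    if stat == "mean":
        return track.mean_over(region)
    raise ValueError(f"unknown height statistic {stat!r}")


def _peak_height(peak: Peak, track: Optional[SignalTrack], stat: str) -> float:
    if track is None:
        return peak.height
    return region_height(peak.interval, track, stat)


def differential_accessibility(
    ctl_peaks: Sequence[Peak],
    reg_peaks: Sequence[Peak],
    ctl_track: Optional[SignalTrack] = None,
    reg_track: Optional[SignalTrack] = None,
    theta: float = 1.5,
    eps: float = 0.01,
    timepoint: str = "",
    stat: str = "max",
) -> List[DiffRegion]:
    """Regions more accessible in regeneration (regeneration-higher only).

    Inputs are concordant peak sets.  A regeneration peak overlapping no
    control peak yields a presence_only region; one overlapping >= 1 control
    peak is kept iff (h_reg + eps) / (max control h + eps) >= theta.  Heights
    come from the tracks when given, else from the stored peak heights.
    """
    ctl_by_chrom = _sort_by_position(ctl_peaks)
    out: List[DiffRegion] = []
    for p in reg_peaks:
        partners = _overlapping_peaks(p, ctl_by_chrom)
        if not partners:
            out.append(DiffRegion(p.interval, p.summit, "presence_only",
                                  timepoint=timepoint))
            continue
        h_reg = _peak_height(p, reg_track, stat)
        h_ctl = max(_peak_height(q, ctl_track, stat) for q in partners)
        fold = (h_reg + eps) / (h_ctl + eps)
        if fold >= theta:
            out.append(DiffRegion(p.interval, p.summit, "height_fold",
                                  fold=fold, timepoint=timepoint))
    return out


def classify_drre(
    diff: DiffRegion, ctl_open: RegionSet, l3_open: RegionSet
) -> str:
    """Emerging iff the region overlaps neither prior open set.

    Any prior openness — in the same-timepoint control open regions or in
    the untreated L3 open regions — disqualifies "open only after damage",
    so mixed cases classify as increasing.
    """
    if ctl_open.overlaps(diff.interval) or l3_open.overlaps(diff.interval):
        return "increasing"
    return "emerging"


def classify_drres(
    diffs: Sequence[DiffRegion], ctl_open: RegionSet, l3_open: RegionSet
) -> List[DRRE]:
    """Classify every differential region, recording prior-openness provenance."""
    out = []
    for d in diffs:
        in_ctl = ctl_open.overlaps(d.interval)
        in_l3 = l3_open.overlaps(d.interval)
        cls = "increasing" if (in_ctl or in_l3) else "emerging"
        provenance = "+".join(
            name for name, hit in (("ctl", in_ctl), ("l3", in_l3)) if hit
        )
        out.append(DRRE(d, cls, prior_openness=provenance))
    return out
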
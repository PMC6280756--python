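"""Enhancer reusage, summit-anchored profiles and conservation scoring.

Reusage: an emerging DRRE overlapping open chromatin from any other tissue
or developmental stage (FAIRE/embryo-ATAC reference collections) is
*reused*; one overlapping none is *novel*, a candidate regeneration-specific
enhancer.  The assayed condition itself (L3 wing disc) must not appear among
the references.

Profiles: per-offset mean of a signal track around an anchor position
(NF peak summit for conservation, TSS for accessibility aggregation).

Species conservation: for each enhancer and each species alignment mask,
the fraction of bases aligned; a species "presents" the enhancer when that
fraction reaches ``tau`` (0.5 by default — the presence criterion is a
package decision, exposed as a parameter).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .accessibility import DRRE
from .intervals import GenomicInterval, RegionSet
from .signal import SignalTrack

__all__ = [
    "ReferenceSet", "UsageCall", "classify_usage", "classify_usage_all",
    "anchor_profile", "species_conservation", "activity_overlap",
]

ASSAYED = ("L3", "wing")   # the assayed stage/tissue may not be a reference


@dataclass(frozen=True)
class ReferenceSet:
    """A labelled open-region collection from one (stage, tissue) dataset."""

    label: str
    stage: str
    tissue: str
    regions: RegionSet


@dataclass(frozen=True)
class UsageCall:
    drre_id: str
    usage: str                         # "reused" | "novel"
    supporting_datasets: Tuple[str, ...]


def _validate_refs(refs: Sequence[ReferenceSet]) -> None:
    labels = [r.label for r in refs]
    if len(set(labels)) != len(labels):
        raise ValueError("reference set labels must be unique")
    for r in refs:
        if (r.stage, r.tissue) == ASSAYED:
            raise ValueError(
                f"reference {r.label!r} is the assayed condition {ASSAYED}"
            )


def classify_usage(
    drre: Union[DRRE, GenomicInterval],
    refs: Sequence[ReferenceSet],
    drre_id: str = "",
) -> UsageCall:
    """Reused iff the DRRE overlaps >= 1 reference open-region set."""
    _validate_refs(refs)
    iv = drre if isinstance(drre, GenomicInterval) else drre.interval
    hits = tuple(r.label for r in refs if r.regions.overlaps(iv))
    return UsageCall(drre_id, "reused" if hits else "novel", hits)


def classify_usage_all(
    drres: Sequence[DRRE], refs: Sequence[ReferenceSet]
) -> List[DRRE]:
    """Attach a UsageCall to every DRRE (and return them)."""
    _validate_refs(refs)
    for i, d in enumerate(drres):
        call = classify_usage(d, refs, drre_id=f"drre_{i + 1:04d}")
        d.usage = call
    return list(drres)


def anchor_profile(
    anchors: Sequence[Tuple[str, int]],
    track: SignalTrack,
    flank: int = 500,
) -> pd.DataFrame:
    """Positionwise mean track value at offsets -flank..+flank around anchors.

    ``anchors`` are (chrom, position) pairs — NF peak summits for
    conservation profiles, TSSs for accessibility aggregation.  Returns a
    DataFrame with columns offset, mean, n.
    """
    offsets = np.arange(-flank, flank + 1)
    if not anchors:
        return pd.DataFrame(columns=["offset", "mean", "n"])
    acc = np.zeros(len(offsets))
    for chrom, pos in anchors:
        acc += track.values_at(chrom, pos + offsets)
    return pd.DataFrame({
        "offset": offsets,
        "mean": acc / len(anchors),
        "n": len(anchors),
    })


def summit_anchors(drres: Sequence[DRRE]) -> List[Tuple[str, int]]:
    return [(d.interval.chrom, d.summit) for d in drres]


def species_conservation(
    drre: Union[DRRE, GenomicInterval],
    masks: Dict[str, RegionSet],
    tau: float = 0.5,
) -> Tuple[int, float]:
    """(n_species presenting the enhancer, mean percent of aligned bases).

    A species presents the enhancer when its aligned fraction over the
    enhancer is >= tau.  percent_aligned is 100 x the mean aligned fraction
    over all species (one summary point per enhancer).
    """
    if not masks:
        raise ValueError("need at least one species alignment mask")
    iv = drre if isinstance(drre, GenomicInterval) else drre.interval
    fracs = np.array([
        masks[s].covered_bases(iv) / iv.length for s in masks
    ])
    return int(np.sum(fracs >= tau)), float(100.0 * fracs.mean())


def activity_overlap(
    drres: Sequence[Union[DRRE, GenomicInterval]],
    activity_regions: RegionSet,
) -> Optional[float]:
    """Percentage of DRREs overlapping >= 1 activity (STARR-seq) region.

    None for an empty input (undefined).
    """
    if not drres:
        return None
    ivs = [d if isinstance(d, GenomicInterval) else d.interval for d in drres]
    hits = sum(activity_regions.overlaps(iv) for iv in ivs)
    return 100.0 * hits / len(ivs)
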
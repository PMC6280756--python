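"""Active-enhancer feature marking and qPCR fold-enrichment (ΔΔCt).

Each DRRE is scored for three active-enhancer features — H3K4me1, H3K27ac
and Pol II — against regeneration ChIP data:

* marked         — a regeneration ChIP peak falls within 500 bp up/downstream
                   of the ATAC peak;
* higher_signal  — no peak, but strictly higher mean ChIP signal over the
                   DRRE in regeneration than in control;
* not_marked     — neither.

A DRRE shows enhancer-activity *presence* when at least one feature is
marked or has higher signal, *absence* when all three are not_marked.

ΔΔCt quantification for ChIP-qPCR (and, with a known-interaction region as
the reference, 3C-qPCR): ΔCt = mean Ct(target) - mean Ct(reference) per
condition; fold = 2^-(ΔCt(regeneration) - ΔCt(control)), with the SEM
propagated from technical-replicate spread.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .accessibility import DRRE, Peak
from .intervals import GenomicInterval, RegionSet
from .signal import SignalTrack

FEATURES = ("H3K4me1", "H3K27ac", "PolII")
STATUSES = ("marked", "higher_signal", "not_marked")

__all__ = ["FEATURES", "ActivityCall", "feature_status", "activity_call",
           "call_activity_all", "ddct_fold_enrichment"]


@dataclass(frozen=True)
class ActivityCall:
    drre_id: str
    activity: str                        # "presence" | "absence"
    statuses: Tuple[Tuple[str, str], ...]  # (feature, status) pairs

    @property
    def n_features_present(self) -> int:
        return sum(1 for _, s in self.statuses if s != "not_marked")


def feature_status(
    drre: Union[DRRE, GenomicInterval],
    feature_peaks: Union[RegionSet, Sequence[GenomicInterval]],
    reg_track: Optional[SignalTrack] = None,
    ctl_track: Optional[SignalTrack] = None,
    window: int = 500,
) -> str:
    """Status of one feature at one DRRE (see module docstring)."""
    iv = drre if isinstance(drre, GenomicInterval) else drre.interval
    peaks = (feature_peaks if isinstance(feature_peaks, RegionSet)
             else RegionSet(feature_peaks))
    expanded = GenomicInterval(iv.chrom, max(0, iv.start - window), iv.end + window)
    if peaks.overlaps(expanded):
        return "marked"
    reg_mean = reg_track.mean_over(iv) if reg_track is not None else 0.0
    ctl_mean = ctl_track.mean_over(iv) if ctl_track is not None else 0.0
    if reg_mean > ctl_mean:   # strict: a tie is not higher signal
        return "higher_signal"
    return "not_marked"


def activity_call(statuses: Dict[str, str], drre_id: str = "") -> ActivityCall:
    """Presence iff >= 1 feature is marked or has higher signal."""
    missing = set(FEATURES) - set(statuses)
    if missing:
        raise ValueError(f"missing feature statuses: {sorted(missing)}")
    pairs = tuple((f, statuses[f]) for f in FEATURES)
    presence = any(s != "not_marked" for _, s in pairs)
    return ActivityCall(drre_id, "presence" if presence else "absence", pairs)


def call_activity_all(
    drres: Sequence[DRRE],
    chip_peaks: Dict[str, Union[RegionSet, Sequence[GenomicInterval]]],
    reg_tracks: Optional[Dict[str, SignalTrack]] = None,
    ctl_tracks: Optional[Dict[str, SignalTrack]] = None,
    window: int = 500,
) -> List[DRRE]:
    """Score all three features and attach an ActivityCall to every DRRE."""
    peak_sets = {
        f: (p if isinstance(p, RegionSet) else RegionSet(p))
        for f, p in chip_peaks.items()
    }
    for i, d in enumerate(drres):
        statuses = {}
        for f in FEATURES:
            statuses[f] = feature_status(
                d, peak_sets.get(f, RegionSet()),
                (reg_tracks or {}).get(f), (ctl_tracks or {}).get(f),
                window,
            )
        d.activity = activity_call(statuses, drre_id=f"drre_{i + 1:04d}")
    return list(drres)


def _cell(table: pd.DataFrame, region: str, condition: str, role: str):
    sub = table[(table.region_id == region)
                & (table.condition == condition)
                & (table.role == role)]
    if sub.empty:
        raise ValueError(f"qPCR table missing {region}/{condition}/{role}")
    ct = sub.ct.astype(float).values
    if np.any(ct <= 0):
        raise ValueError("Ct values must be positive")
    mean = float(np.mean(ct))
    var_of_mean = float(np.var(ct, ddof=1) / len(ct)) if len(ct) > 1 else 0.0
    return mean, var_of_mean


def ddct_fold_enrichment(table: pd.DataFrame, region: str) -> Dict[str, float]:
    """Fold-change enrichment (regeneration vs control) by the ΔΔCt method.

    ``table`` columns: region_id, condition (control/regeneration), role
    (target/reference), replicate, ct.  The reference role is the input for
    ChIP-qPCR or a known interaction for 3C-qPCR.  Returns fold, sem and
    ddct; SEM is propagated to the fold scale by the delta method.
    """
    means = {}
    variances = []
    for condition in ("control", "regeneration"):
        mt, vt = _cell(table, region, condition, "target")
        mr, vr = _cell(table, region, condition, "reference")
        means[condition] = mt - mr
        variances += [vt, vr]
    ddct = means["regeneration"] - means["control"]
    fold = 2.0 ** (-ddct)
    se_ddct = math.sqrt(sum(variances))
    sem = fold * math.log(2.0) * se_ddct
    return {"fold": fold, "sem": sem, "ddct": ddct}
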
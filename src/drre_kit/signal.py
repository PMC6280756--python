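"""Step-function signal tracks with bedGraph semantics.

A track stores, per chromosome, sorted non-overlapping steps each carrying a
non-negative value (read-depth-normalized ATAC/ChIP signal, or a phastCons
conservation score).  Positions not covered by any step read as 0.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np

from .intervals import GenomicInterval

__all__ = ["SignalTrack"]


class SignalTrack:
    """Piecewise-constant, non-negative genomic signal."""

    def __init__(self, steps: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._steps: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in steps.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError(f"{chrom}: ragged step arrays")
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: empty or inverted step")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping or unsorted steps")
            if np.any(values < 0):
                raise ValueError(f"{chrom}: negative signal value")
            self._steps[chrom] = (starts, ends, values)

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, int, int, float]]
    ) -> "SignalTrack":
        """Build from (chrom, start, end, value) rows in any order."""
        per: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            per.setdefault(chrom, []).append((int(start), int(end), float(value)))
        steps = {}
        for chrom, rows in per.items():
            rows.sort()
            s, e, v = zip(*rows)
            steps[chrom] = (np.asarray(s), np.asarray(e), np.asarray(v))
        return cls(steps)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._steps)

    def records(self) -> Iterable[Tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._steps[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Signal value at each base position; uncovered positions read 0."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(positions.shape, dtype=float)
        step = self._steps.get(chrom)
        if step is None:
            return out
        starts, ends, values = step
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[ok] = values[idx[ok]]
        return out

    def value_at(self, chrom: str, position: int) -> float:
        return float(self.values_at(chrom, np.asarray([position]))[0])

    def _overlapping(self, iv: GenomicInterval):
        step = self._steps.get(iv.chrom)
        if step is None:
            return None
        starts, ends, values = step
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        if hi <= lo:
            return None
        s = np.maximum(starts[lo:hi], iv.start)
        e = np.minimum(ends[lo:hi], iv.end)
        return s, e, values[lo:hi]

    def max_over(self, iv: GenomicInterval) -> float:
        """Maximum per-base value over the interval (0 if any base uncovered)."""
        clipped = self._overlapping(iv)
        if clipped is None:
            return 0.0
        s, e, v = clipped
        peak = float(np.max(v))
        covered = int(np.sum(e - s))
        if covered < iv.length:  # a gap contributes value 0
            peak = max(peak, 0.0)
        return peak

    def mean_over(self, iv: GenomicInterval) -> float:
        """Mean per-base value over the interval; uncovered bases count as 0."""
        clipped = self._overlapping(iv)
        if clipped is None:
            return 0.0
        s, e, v = clipped
        return float(np.sum((e - s) * v) / iv.length)
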
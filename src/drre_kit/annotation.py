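"""TSS-relative genomic annotation of peaks with a fixed precedence order.

Each peak receives exactly one category, decided by its summit position
(interval midpoint when no summit is available), testing in order:

1. CP       — within +/- 100 bp of any gene's TSS (core promoter);
2. FI       — inside any gene's first intron (between projected exons 1/2);
3. proximal — within +/- 2 kb of any TSS;
4. distal   — anything else (assigned to the nearest-TSS gene).

Windows are unstranded on the genome; the reported distance is signed
relative to the assigned gene's strand (negative = upstream of the TSS).
The CP window is configurable because the zebrafish arm of the analysis
uses 0.5 kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .accessibility import DRRE, DiffRegion, Peak
from .genes import GeneModel
from .intervals import GenomicInterval

CATEGORIES = ("CP", "FI", "proximal", "distal")

__all__ = ["AnnotationCategory", "GeneIndex", "annotate_peak",
           "annotate_drres", "annotation_spectrum", "CATEGORIES"]


@dataclass(frozen=True)
class AnnotationCategory:
    category: str
    gene_id: Optional[str]
    distance_to_tss: Optional[int]   # signed, negative = 5' of the TSS


class GeneIndex:
    """Per-chromosome TSS and first-intron lookup tables."""

    def __init__(self, genes: Iterable[GeneModel]):
        per: Dict[str, List[GeneModel]] = {}
        for g in genes:
            per.setdefault(g.chrom, []).append(g)
        self._tss: Dict[str, Tuple[np.ndarray, List[GeneModel]]] = {}
        self._introns: Dict[str, List[Tuple[GenomicInterval, GeneModel]]] = {}
        for chrom, gs in per.items():
            gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss[chrom] = (np.array([g.tss for g in gs]), gs)
            introns = []
            for g in gs:
                fi = g.first_intron()
                if fi is not None:
                    introns.append((fi, g))
            self._introns[chrom] = introns

    def genes_near(self, chrom: str, pos: int, radius: int) -> List[Tuple[int, GeneModel]]:
        """(signed strand-aware distance, gene) for genes with |pos - TSS| <= radius."""
        entry = self._tss.get(chrom)
        if entry is None:
            return []
        tss, gs = entry
        lo = int(np.searchsorted(tss, pos - radius, "left"))
        hi = int(np.searchsorted(tss, pos + radius, "right"))
        out = []
        for g in gs[lo:hi]:
            out.append((_signed_distance(pos, g), g))
        return out

    def first_intron_hits(self, chrom: str, pos: int) -> List[GeneModel]:
        return [g for fi, g in self._introns.get(chrom, []) if fi.contains(pos)]

    def nearest(self, chrom: str, pos: int) -> Optional[Tuple[int, GeneModel]]:
        entry = self._tss.get(chrom)
        if entry is None:
            return None
        tss, gs = entry
        i = int(np.searchsorted(tss, pos))
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(gs):
                cand = (abs(pos - tss[j]), gs[j].gene_id, gs[j])
                if best is None or cand[:2] < best[:2]:
                    best = cand
        # neighbours can tie through duplicates on sorted TSS; scan ties
        if best is None:
            return None
        return _signed_distance(pos, best[2]), best[2]


def _signed_distance(pos: int, gene: GeneModel) -> int:
    """Signed bp from TSS; negative when ``pos`` is 5' (upstream) of the gene."""
    d = pos - gene.tss
    return d if gene.strand == "+" else -d


def _summit_of(peak) -> Tuple[str, int]:
    if isinstance(peak, GenomicInterval):
        return peak.chrom, peak.midpoint
    iv = peak.interval
    summit = getattr(peak, "summit", None)
    return iv.chrom, (summit if summit is not None else iv.midpoint)


def _pick(cands: List[Tuple[int, GeneModel]]) -> Tuple[int, GeneModel]:
    """Nearest TSS wins; residual ties break on lexicographic gene id."""
    return min(cands, key=lambda t: (abs(t[0]), t[1].gene_id))


def annotate_peak(
    peak: Union[Peak, DiffRegion, DRRE, GenomicInterval],
    genes: Union[GeneIndex, Iterable[GeneModel]],
    cp_window: int = 100,
    prox_window: int = 2000,
) -> AnnotationCategory:
    """Unique genomic category for one peak/DRRE by summit precedence."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    chrom, pos = _summit_of(peak)

    cp = index.genes_near(chrom, pos, cp_window)
    if cp:
        d, g = _pick(cp)
        return AnnotationCategory("CP", g.gene_id, d)

    fi = index.first_intron_hits(chrom, pos)
    if fi:
        g = min(fi, key=lambda g: (abs(_signed_distance(pos, g)), g.gene_id))
        return AnnotationCategory("FI", g.gene_id, _signed_distance(pos, g))

    prox = index.genes_near(chrom, pos, prox_window)
    if prox:
        d, g = _pick(prox)
        return AnnotationCategory("proximal", g.gene_id, d)

    nearest = index.nearest(chrom, pos)
    if nearest is None:
        return AnnotationCategory("distal", None, None)
    d, g = nearest
    return AnnotationCategory("distal", g.gene_id, d)


def annotate_drres(
    drres: Sequence[DRRE],
    genes: Union[GeneIndex, Iterable[GeneModel]],
    cp_window: int = 100,
    prox_window: int = 2000,
) -> List[DRRE]:
    """Annotate DRREs in place (and return them)."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    for d in drres:
        d.annotation = annotate_peak(d, index, cp_window, prox_window)
    return list(drres)


def annotation_spectrum(
    drres: Sequence[DRRE], exclude_cp: bool = False
) -> pd.DataFrame:
    """Counts and per-class fractions of annotation categories per DRRE class.

    ``exclude_cp=True`` restricts to the enhancer-only spectrum
    (FI/proximal/distal).
    """
    cats = [c for c in CATEGORIES if not (exclude_cp and c == "CP")]
    rows = []
    for d in drres:
        if d.annotation is None:
            raise ValueError("annotate_drres must run before annotation_spectrum")
        if exclude_cp and d.annotation.category == "CP":
            continue
        rows.append((d.drre_class, d.annotation.category))
    if not rows:
        return pd.DataFrame(columns=["drre_class", "category", "count", "fraction"])
    df = pd.DataFrame(rows, columns=["drre_class", "category"])
    counts = (df.value_counts().rename("count").reset_index())
    counts["fraction"] = counts["count"] / counts.groupby("drre_class")["count"].transform("sum")
    order = {c: i for i, c in enumerate(cats)}
    counts = counts.sort_values(
        ["drre_class", "category"],
        key=lambda s: s.map(order) if s.name == "category" else s,
    ).reset_index(drop=True)
    return counts
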
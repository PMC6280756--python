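"""Gene models: strand-aware TSS, projected exons and the first intron.

The "projected exons" of a gene are the merged exons of all its annotated
transcripts; the first intron (FI) is the gap between the first and second
projected exons in transcriptional (5'->3') order.  A multi-transcript gene
has a single TSS: the 5'-most transcript start over all transcripts, so
annotation relative to the TSS is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .intervals import GenomicInterval, merge_intervals

__all__ = ["GeneModel"]


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts, each a sorted tuple of exons."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: Tuple[Tuple[GenomicInterval, ...], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene model needs >= 1 transcript")
        for t in self.transcripts:
            if not t:
                raise ValueError(f"{self.gene_id}: empty transcript")
            for i, exon in enumerate(t):
                if exon.chrom != self.chrom:
                    raise ValueError(
                        f"{self.gene_id}: exon on {exon.chrom}, gene on {self.chrom}"
                    )
                if i and exon.start < t[i - 1].end:
                    raise ValueError(
                        f"{self.gene_id}: transcript exons unsorted or overlapping"
                    )

    @classmethod
    def from_exon_lists(
        cls, gene_id: str, chrom: str, strand: str,
        transcripts: Sequence[Sequence[GenomicInterval]],
    ) -> "GeneModel":
        return cls(
            gene_id, chrom, strand,
            tuple(tuple(sorted(t)) for t in transcripts),
        )

    @property
    def tss(self) -> int:
        """Transcription start site (base position, 0-based).

        5'-most start over all transcripts: min start on '+', the last base
        (end - 1) of the right-most exon on '-'.
        """
        if self.strand == "+":
            return min(t[0].start for t in self.transcripts)
        return max(t[-1].end for t in self.transcripts) - 1

    @property
    def interval(self) -> GenomicInterval:
        start = min(t[0].start for t in self.transcripts)
        end = max(t[-1].end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end)

    def projected_exons(self) -> Tuple[List[GenomicInterval], Optional[GenomicInterval]]:
        """Merged exons over all transcripts, ordered 5'->3', plus the FI.

        Returns ``(exons, first_intron)``; ``first_intron`` is None when the
        merge leaves fewer than two projected exons.
        """
        merged = merge_intervals(e for t in self.transcripts for e in t)
        if self.strand == "-":
            ordered = merged[::-1]
        else:
            ordered = merged
        if len(merged) < 2:
            return ordered, None
        a, b = ordered[0], ordered[1]
        lo, hi = (a.end, b.start) if self.strand == "+" else (b.end, a.start)
        return ordered, GenomicInterval(self.chrom, lo, hi)

    def first_intron(self) -> Optional[GenomicInterval]:
        return self.projected_exons()[1]
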
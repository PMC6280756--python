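"""Readers and writers for the plain-text formats the pipeline consumes.

Formats: BED3 regions, BED6+2 peaks (name, score, strand, summit, height),
a gene/transcript/exon GTF subset, bedGraph signal, and tab-delimited tables
with a header row.  GTF coordinates (1-based, inclusive) are converted to
the internal 0-based half-open convention on read and restored on write, so
a read-write-read round trip is lossless.  All interval outputs are sorted
by (chrom, start).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import pandas as pd

from .accessibility import Peak
from .genes import GeneModel
from .intervals import GenomicInterval
from .signal import SignalTrack

PathLike = Union[str, Path]

__all__ = [
    "read_bed", "write_bed",
    "read_peaks", "write_peaks",
    "read_bedgraph", "write_bedgraph",
    "read_gtf", "write_gtf",
    "read_table", "write_table",
]


# ---------------------------------------------------------------- BED3 / BED6

def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Read the first three columns of a BED file as intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(chrom, int(start), int(end)))
    return sorted(out)


def write_bed(path: PathLike, intervals: Iterable[GenomicInterval],
              names: Sequence[str] | None = None) -> None:
    ivs = list(intervals)
    order = sorted(range(len(ivs)), key=lambda i: ivs[i])
    with open(path, "w") as fh:
        for i in order:
            iv = ivs[i]
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")


# ------------------------------------------------------------- peaks (BED6+2)

def read_peaks(path: PathLike) -> List[Peak]:
    """Read a BED6+2 peak file: chrom start end name score strand summit height."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            out.append(Peak(
                GenomicInterval(f[0], int(f[1]), int(f[2])),
                summit=int(f[6]), height=float(f[7]), sample_id=f[3],
            ))
    return sorted(out, key=lambda p: p.interval)


def write_peaks(path: PathLike, peaks: Iterable[Peak]) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks, key=lambda p: p.interval):
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.sample_id or '.'}\t0\t.\t"
                f"{p.summit}\t{p.height:g}\n"
            )


# ------------------------------------------------------------------- bedGraph

def read_bedgraph(path: PathLike) -> SignalTrack:
    rows: List[Tuple[str, int, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            rows.append((chrom, int(start), int(end), float(value)))
    return SignalTrack.from_records(rows)


def write_bedgraph(path: PathLike, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ------------------------------------------------------------------ GTF subset

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _attrs(field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: PathLike) -> List[GeneModel]:
    """Read gene models from a GTF subset (exon features define structure).

    Only ``exon`` features are required; ``gene``/``transcript`` lines are
    tolerated.  Strand and chromosome come from the exon lines.
    """
    exons: Dict[str, Dict[str, List[GenomicInterval]]] = {}
    meta: Dict[str, Tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = _attrs(f[8])
            gid, tid = attrs["gene_id"], attrs["transcript_id"]
            # GTF is 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(f[0], int(f[3]) - 1, int(f[4]))
            exons.setdefault(gid, {}).setdefault(tid, []).append(iv)
            meta[gid] = (f[0], f[6])
    genes = []
    for gid in sorted(exons):
        chrom, strand = meta[gid]
        transcripts = [sorted(exons[gid][tid]) for tid in sorted(exons[gid])]
        genes.append(GeneModel.from_exon_lists(gid, chrom, strand, transcripts))
    return genes


def write_gtf(path: PathLike, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start)):
            span = g.interval
            base = f"{g.chrom}\tdrre_kit\t%s\t%d\t%d\t.\t{g.strand}\t.\t%s\n"
            fh.write(base % ("gene", span.start + 1, span.end,
                             f'gene_id "{g.gene_id}";'))
            for ti, t in enumerate(g.transcripts, 1):
                tid = f"{g.gene_id}.t{ti}"
                tstart, tend = t[0].start, t[-1].end
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                fh.write(base % ("transcript", tstart + 1, tend, attrs))
                for exon in t:
                    fh.write(base % ("exon", exon.start + 1, exon.end, attrs))


# --------------------------------------------------------------------- tables

def read_table(path: PathLike, **kwargs) -> pd.DataFrame:
    """Read a tab-delimited table with a header row."""
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(path: PathLike, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
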
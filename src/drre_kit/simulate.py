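"""Seeded synthetic regeneration study with planted ground truth.

The generator emits a complete toy study — gene models, replicate FPKM
tables, replicate ATAC peak sets with signal tracks, an untreated L3
baseline, FAIRE-like reference open-region collections, ChIP peaks and
tracks, a conservation track, per-species alignment masks, ortholog maps
and injured/uninjured species expression tables — together with a
:class:`SimTruth` bundle recording every planted label, so each pipeline
stage can be tested for exact recovery without any download.

Planted effect sizes deliberately clear the calling thresholds with margin
(differential-expression folds >= 2 against the 1.7 rule, accessibility
folds >= 2 against the 1.5 rule, background height noise capped below a
1.2-fold swing) so that the threshold rules recover the planted truth
deterministically.  One RNG stream per data layer is derived from the
master seed, so changing one layer's parameters leaves the others
untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as dio
from .accessibility import Peak
from .conservation import ReferenceSet
from .cross_species import SPECIES, OrthologMap
from .expression import TIMEPOINTS, ExpressionMatrix
from .genes import GeneModel
from .intervals import GenomicInterval, RegionSet
from .signal import SignalTrack

__all__ = ["SimConfig", "SimTruth", "StudyBundle", "simulate_study",
           "null_study", "load_bundle"]

# FAIRE-like reference datasets: label -> (stage, tissue); deliberately
# excludes the assayed condition (L3 wing disc).
REFERENCE_DATASETS: Dict[str, Tuple[str, str]] = {
    "embryo_2_4h": ("embryo", "whole"),
    "embryo_6_8h": ("embryo", "whole"),
    "embryo_16_18h": ("embryo", "whole"),
    "L3_cns": ("L3", "cns"),
    "L3_eye_antenna": ("L3", "eye_antenna"),
    "L3_haltere": ("L3", "haltere"),
    "L3_leg": ("L3", "leg"),
    "pharate_haltere": ("pharate", "haltere"),
    "pharate_leg": ("pharate", "leg"),
    "pharate_wing": ("pharate", "wing"),
}

CHIP_FEATURES = ("H3K4me1", "H3K27ac", "PolII")


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator (defaults are the study)."""

    seed: int = 0
    # genome / genes
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 400
    max_transcripts: int = 3
    # expression
    replicates: int = 2
    de_fraction: float = 0.05          # background DE genes per timepoint
    de_up_fraction: float = 0.9        # share of background DE that is up
    de_fold_location: float = math.log(2.5)   # log-normal location, >= log 2
    de_fold_sigma: float = 0.25
    min_de_fold: float = 2.0
    expression_noise_sigma: float = 0.05
    baseline_log_mean: float = math.log(15.0)
    baseline_log_sigma: float = 1.0
    # genomic clusters of up-regulated genes (planted at the early timepoint)
    n_planted_clusters: int = 4
    cluster_genes: int = 5
    cluster_span: int = 20_000         # TSS span of a planted cluster, < window
    # chromatin accessibility (planted at the early timepoint + L3 baseline)
    n_emerging: int = 30
    n_increasing: int = 50
    n_background_peaks: int = 150
    peak_width: int = 400
    background_height_jitter: float = 0.09   # keeps noise folds below 1.2
    increasing_fold_range: Tuple[float, float] = (2.0, 3.0)
    # usage / conservation
    reused_fraction: float = 0.5
    n_reused: Optional[int] = None           # overrides reused_fraction
    ref_background_regions: int = 15         # unrelated regions per reference set
    chip_marked_fraction: float = 0.7
    conserved_increasing_fraction: float = 0.5
    conservation_background: float = 0.1
    conservation_peak: float = 0.8
    conservation_halfwidth: int = 200
    n_species_masks: int = 10
    # cross-species
    ortholog_density: float = 0.6
    n_core_genes: int = 12
    n_fragments: int = 2000

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0 <= self.reused_fraction <= 1:
            raise ValueError("reused_fraction must be in [0, 1]")
        if self.cluster_span >= 30_000:
            raise ValueError("cluster_span must fit inside one 30-kb window")


@dataclass
class SimTruth:
    """Planted labels, keyed consistently with the emitted data."""

    de: Dict[str, Dict[str, str]]                      # tp -> gene -> up/down
    clusters: List[Dict]                               # planted cluster records
    region_classes: Dict[str, str]                     # region id -> class
    regions: Dict[str, GenomicInterval]                # region id -> interval
    summits: Dict[str, int]
    reused_ids: Set[str]                               # subset of emerging ids
    marked_features: Dict[str, FrozenSet[str]]         # drre id -> features
    core_genes: Set[str]
    fish_up: Set[str]
    mouse_up: Set[str]

    def region_id_at(self, interval: GenomicInterval) -> Optional[str]:
        for rid, iv in self.regions.items():
            if iv == interval:
                return rid
        return None

    def drre_ids(self) -> List[str]:
        return [r for r, c in self.region_classes.items()
                if c in ("emerging", "increasing")]


@dataclass
class StudyBundle:
    """In-memory synthetic study; `write` emits the on-disk text formats."""

    config: SimConfig
    truth: SimTruth
    genes: List[GeneModel]
    expression: ExpressionMatrix
    atac_peaks: Dict[Tuple, List[Peak]]       # (condition, tp, rep) or ("L3", rep)
    atac_tracks: Dict[str, SignalTrack]       # "control_early", "regeneration_early", "L3"
    reference_sets: List[ReferenceSet]
    chip_peaks: Dict[str, List[GenomicInterval]]
    chip_reg_tracks: Dict[str, SignalTrack]
    chip_ctl_tracks: Dict[str, SignalTrack]
    conservation: SignalTrack
    species_masks: Dict[str, RegionSet]
    ortholog_map: OrthologMap
    species_expression: Dict[str, pd.DataFrame]   # gene/injured/uninjured
    fragment_lengths: np.ndarray

    def write(self, outdir) -> Dict[str, str]:
        out = Path(outdir)
        for sub in ("peaks", "tracks", "refs", "chip", "masks", "truth"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        paths: Dict[str, str] = {}

        def _p(key: str, rel: str) -> Path:
            paths[key] = rel
            return out / rel

        dio.write_gtf(_p("genes", "genes.gtf"), self.genes)
        self.expression.to_tsv(_p("expression", "expression.tsv"))
        for key, peaks in sorted(self.atac_peaks.items()):
            name = "atac_" + "_".join(str(k) for k in key)
            dio.write_peaks(_p(name, f"peaks/{name}.bed"), peaks)
        for name, track in sorted(self.atac_tracks.items()):
            dio.write_bedgraph(_p(f"track_{name}", f"tracks/atac_{name}.bedgraph"), track)
        ref_rows = []
        for ref in self.reference_sets:
            rel = f"refs/{ref.label}.bed"
            dio.write_bed(_p(f"ref_{ref.label}", rel), ref.regions.intervals)
            ref_rows.append((ref.label, ref.stage, ref.tissue, rel))
        pd.DataFrame(ref_rows, columns=["label", "stage", "tissue", "path"]) \
            .to_csv(_p("ref_manifest", "refs/manifest.tsv"), sep="\t", index=False)
        for feat in CHIP_FEATURES:
            dio.write_bed(_p(f"chip_{feat}", f"chip/{feat}_regeneration_peaks.bed"),
                          self.chip_peaks[feat])
            dio.write_bedgraph(_p(f"chip_{feat}_reg", f"chip/{feat}_regeneration.bedgraph"),
                               self.chip_reg_tracks[feat])
            dio.write_bedgraph(_p(f"chip_{feat}_ctl", f"chip/{feat}_control.bedgraph"),
                               self.chip_ctl_tracks[feat])
        dio.write_bedgraph(_p("conservation", "conservation.bedgraph"), self.conservation)
        mask_rows = []
        for sp in sorted(self.species_masks):
            rel = f"masks/{sp}.bed"
            dio.write_bed(_p(f"mask_{sp}", rel), self.species_masks[sp].intervals)
            mask_rows.append((sp, rel))
        pd.DataFrame(mask_rows, columns=["species", "path"]) \
            .to_csv(_p("mask_manifest", "masks/manifest.tsv"), sep="\t", index=False)
        self.ortholog_map.to_tsv(_p("orthologs", "orthologs.tsv"))
        for sp in SPECIES:
            self.species_expression[sp].to_csv(
                _p(f"expr_{sp}", f"expression_{sp}.tsv"), sep="\t", index=False)
        pd.DataFrame({"length": self.fragment_lengths}).to_csv(
            _p("fragments", "fragments.tsv"), sep="\t", index=False)
        self._write_truth(out)
        return paths

    def _write_truth(self, out: Path) -> None:
        t = self.truth
        rows = [(tp, g, d) for tp in sorted(t.de) for g, d in sorted(t.de[tp].items())]
        pd.DataFrame(rows, columns=["timepoint", "gene_id", "direction"]) \
            .to_csv(out / "truth/de_genes.tsv", sep="\t", index=False)
        rows = [
            (i + 1, c["chrom"], c["timepoint"], c["direction"], ",".join(c["members"]))
            for i, c in enumerate(t.clusters)
        ]
        pd.DataFrame(rows, columns=["cluster", "chrom", "timepoint", "direction",
                                    "members"]) \
            .to_csv(out / "truth/clusters.tsv", sep="\t", index=False)
        rows = [
            (rid, t.regions[rid].chrom, t.regions[rid].start, t.regions[rid].end,
             t.summits[rid], cls,
             ("reused" if rid in t.reused_ids else "novel") if cls == "emerging" else "",
             ",".join(sorted(t.marked_features.get(rid, ()))))
            for rid, cls in sorted(t.region_classes.items())
        ]
        pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "summit",
                                    "class", "usage", "marked_features"]) \
            .to_csv(out / "truth/regions.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": sorted(t.core_genes)}) \
            .to_csv(out / "truth/core_genes.tsv", sep="\t", index=False)


# --------------------------------------------------------------------------
# generator internals

def _layer_rngs(seed: int) -> Dict[str, np.random.Generator]:
    layers = ("genome", "expression", "peaks", "usage", "chip",
              "conservation", "orthologs", "fragments")
    children = np.random.SeedSequence(seed).spawn(len(layers))
    return {name: np.random.default_rng(ss) for name, ss in zip(layers, children)}


def _make_gene(gene_id: str, chrom: str, tss: int, strand: str,
               rng: np.random.Generator, max_transcripts: int) -> GeneModel:
    body = int(rng.integers(2000, 5000))
    n_exons = int(rng.integers(2, 4))
    # split the body into exons separated by introns
    cuts = np.sort(rng.uniform(0.15, 0.85, size=2 * (n_exons - 1)))
    bounds = np.concatenate([[0.0], cuts, [1.0]])
    pieces = [(int(bounds[i] * body), int(bounds[i + 1] * body))
              for i in range(0, len(bounds) - 1, 2)]
    pieces = [(a, b) for a, b in pieces if b - a >= 50]
    if strand == "+":
        exons = [GenomicInterval(chrom, tss + a, tss + b) for a, b in pieces]
    else:
        exons = sorted(
            GenomicInterval(chrom, tss - b + 1, tss - a + 1) for a, b in pieces
        )
    transcripts = [exons]
    n_tx = int(rng.integers(1, max_transcripts + 1))
    if n_tx >= 2 and len(exons) >= 2:
        # an isoform skipping the 3'-most exon
        transcripts.append(exons[1:] if strand == "-" else exons[:-1])
    if n_tx >= 3 and len(exons) >= 2:
        # an isoform with a shortened 5' exon (TSS stays the 5'-most overall)
        first = exons[0] if strand == "+" else exons[-1]
        delta = min(40, first.length - 20)
        if strand == "+":
            short = GenomicInterval(chrom, first.start + delta, first.end)
            transcripts.append([short] + exons[1:])
        else:
            short = GenomicInterval(chrom, first.start, first.end - delta)
            transcripts.append(exons[:-1] + [short])
    return GeneModel.from_exon_lists(gene_id, chrom, strand, transcripts)


def _place_genes(cfg: SimConfig, rng: np.random.Generator):
    """Genes on a jittered grid; planted clusters compress TSS spacing.

    Returns (genes, positions df rows, cluster truth records, exclusion ids).
    """
    per_chrom = cfg.n_genes // cfg.n_chroms
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    spacing = cfg.chrom_length // (per_chrom + 1)

    # choose cluster anchor slots, round-robin over chromosomes
    cluster_slots: Dict[Tuple[str, int], int] = {}  # (chrom, slot) -> cluster idx
    anchors: List[Tuple[str, int]] = []
    for ci in range(cfg.n_planted_clusters):
        chrom = chroms[ci % len(chroms)]
        while True:
            s0 = int(rng.integers(3, per_chrom - cfg.cluster_genes - 3))
            slots = range(s0, s0 + cfg.cluster_genes)
            buffer = range(s0 - 3, s0 + cfg.cluster_genes + 3)
            if all((chrom, s) not in cluster_slots for s in buffer):
                for s in slots:
                    cluster_slots[(chrom, s)] = ci
                anchors.append((chrom, s0))
                break

    genes: List[GeneModel] = []
    cluster_members: Dict[int, List[str]] = {i: [] for i in range(cfg.n_planted_clusters)}
    cluster_windows: Dict[int, Tuple[str, int, int]] = {}
    gid = 0
    for chrom in chroms:
        for slot in range(per_chrom):
            gid += 1
            gene_id = f"g{gid:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            ci = cluster_slots.get((chrom, slot))
            if ci is not None:
                chrom_a, s0 = anchors[ci]
                j = slot - s0
                step = cfg.cluster_span // max(cfg.cluster_genes - 1, 1)
                base = spacing * (s0 + 1)
                tss = base + j * step
                cluster_members[ci].append(gene_id)
                lo = min(cluster_windows.get(ci, (chrom, base, base))[1], tss)
                hi = max(cluster_windows.get(ci, (chrom, base, base))[2], tss)
                cluster_windows[ci] = (chrom, lo, hi)
            else:
                jitter = int(rng.integers(-spacing // 8, spacing // 8 + 1))
                tss = spacing * (slot + 1) + jitter
            tss = int(np.clip(tss, 6000, cfg.chrom_length - 6000))
            genes.append(_make_gene(gene_id, chrom, tss, strand, rng,
                                    cfg.max_transcripts))

    cluster_truth = [
        {
            "chrom": cluster_windows[ci][0],
            "members": tuple(cluster_members[ci]),
            "timepoint": "early",
            "direction": "up",
        }
        for ci in range(cfg.n_planted_clusters)
    ]

    # genes inside cluster windows +/- one full window are excluded from
    # background DE planting, so planted membership is unambiguous
    excluded: Set[str] = set()
    window = 30_000
    for ci, (chrom, lo, hi) in cluster_windows.items():
        for g in genes:
            if g.chrom == chrom and lo - window <= g.tss <= hi + window:
                excluded.add(g.gene_id)
    return genes, cluster_truth, cluster_members, excluded


def _plant_expression(cfg: SimConfig, rng: np.random.Generator,
                      genes: List[GeneModel],
                      cluster_members: Dict[int, List[str]],
                      excluded: Set[str]):
    gene_ids = [g.gene_id for g in genes]
    de: Dict[str, Dict[str, str]] = {tp: {} for tp in TIMEPOINTS}

    cluster_genes = {g for members in cluster_members.values() for g in members}
    for g in cluster_genes:
        de["early"][g] = "up"

    eligible = [g for g in gene_ids if g not in excluded]
    core = sorted(rng.choice(eligible, size=cfg.n_core_genes, replace=False))
    for g in core:
        de["early"][g] = "up"
        de["mid"][g] = "up"

    remaining = [g for g in eligible if g not in core]
    n_bg = round(cfg.de_fraction * len(remaining))
    for tp in TIMEPOINTS:
        chosen = rng.choice(remaining, size=n_bg, replace=False)
        n_up = round(cfg.de_up_fraction * n_bg)
        for i, g in enumerate(chosen):
            de[tp].setdefault(g, "up" if i < n_up else "down")

    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sigma,
                                 size=len(gene_ids)))
    planted_any = {g for tp in TIMEPOINTS for g in de[tp]}
    for i, g in enumerate(gene_ids):
        if g in planted_any:
            baseline[i] = max(baseline[i], 0.5)

    folds = {
        (tp, g): max(cfg.min_de_fold,
                     float(np.exp(rng.normal(cfg.de_fold_location, cfg.de_fold_sigma))))
        for tp in TIMEPOINTS for g in de[tp]
    }

    cols = {}
    for cond in ("control", "regeneration"):
        for tp in TIMEPOINTS:
            for rep in range(1, cfg.replicates + 1):
                mean = baseline.copy()
                if cond == "regeneration":
                    for i, g in enumerate(gene_ids):
                        d = de[tp].get(g)
                        if d == "up":
                            mean[i] *= folds[(tp, g)]
                        elif d == "down":
                            mean[i] /= folds[(tp, g)]
                noise = np.exp(rng.normal(0.0, cfg.expression_noise_sigma,
                                          size=len(gene_ids)))
                cols[f"{cond}_{tp}_{rep}"] = mean * noise
    expr = ExpressionMatrix(pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id")))
    return expr, de, set(core)


class _LocusAllocator:
    """Non-overlapping peak loci with spacing wide enough that the 500-bp
    ChIP marking window of one locus cannot reach a neighbour."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.centers: Dict[str, List[int]] = {
            f"chr{i + 1}": [] for i in range(cfg.n_chroms)
        }
        self.min_gap = cfg.peak_width + 1200

    def take(self) -> Tuple[str, int]:
        cfg = self.cfg
        for _ in range(10_000):
            chrom = f"chr{int(self.rng.integers(cfg.n_chroms)) + 1}"
            c = int(self.rng.integers(cfg.peak_width, cfg.chrom_length - cfg.peak_width))
            if all(abs(c - o) >= self.min_gap for o in self.centers[chrom]):
                self.centers[chrom].append(c)
                return chrom, c
        raise RuntimeError(
            "could not place a non-overlapping peak locus; "
            "reduce peak counts or enlarge chrom_length"
        )


def _plant_peaks(cfg: SimConfig, rng: np.random.Generator, null: bool = False):
    """ATAC layer: background / increasing / emerging loci, peaks and tracks."""
    alloc = _LocusAllocator(cfg, rng)
    half = cfg.peak_width // 2
    j = cfg.background_height_jitter

    classes = (["background"] * cfg.n_background_peaks
               + ([] if null else ["increasing"] * cfg.n_increasing
                  + ["emerging"] * cfg.n_emerging))
    region_classes: Dict[str, str] = {}
    regions: Dict[str, GenomicInterval] = {}
    summits: Dict[str, int] = {}
    counters = {"background": 0, "increasing": 0, "emerging": 0}
    prefix = {"background": "bg", "increasing": "in", "emerging": "em"}

    track_rows = {"control_early": [], "regeneration_early": [], "L3": []}
    peaks: Dict[Tuple, List[Peak]] = {}
    for cond in ("control", "regeneration"):
        for rep in (1, 2):
            peaks[(cond, "early", rep)] = []
    for rep in (1, 2):
        peaks[("L3", rep)] = []

    def add_peak(key, iv, summit, height, rid):
        peaks[key].append(Peak(iv, summit, round(height, 4), sample_id=rid))

    for cls in classes:
        chrom, c = alloc.take()
        counters[cls] += 1
        rid = f"{prefix[cls]}_{counters[cls]:04d}"
        iv = GenomicInterval(chrom, c - half, c + half)
        region_classes[rid] = cls
        regions[rid] = iv
        summits[rid] = c
        h = float(rng.uniform(5, 15))
        u = rng.uniform(1 - j, 1 + j, size=3)   # ctl / reg / L3 track noise
        if cls == "background":
            h_ctl, h_l3 = h * u[0], h * u[2]
            h_reg = h * u[1]
        elif cls == "increasing":
            F = float(rng.uniform(*cfg.increasing_fold_range))
            h_ctl, h_l3 = h * u[0], h * u[2]
            h_reg = h * F * u[1]
        else:  # emerging
            h_ctl = h_l3 = 0.0
            h_reg = h * u[1]

        shift = {rep: int(rng.integers(-50, 51)) for rep in (1, 2)}
        shift[1] = 0   # replicate 1 carries the exact planted coordinates

        def reps_for(key, height):
            for rep in (1, 2):
                d = shift[rep]
                add_peak(key[:-1] + (rep,),
                         GenomicInterval(chrom, iv.start + d, iv.end + d),
                         c, height, rid)

        if h_ctl > 0:
            reps_for(("control", "early", 0), h_ctl)
            track_rows["control_early"].append((chrom, iv.start, iv.end, h_ctl))
        if h_l3 > 0:
            reps_for(("L3", 0), h_l3)
            track_rows["L3"].append((chrom, iv.start, iv.end, h_l3))
        if h_reg > 0:
            reps_for(("regeneration", "early", 0), h_reg)
            track_rows["regeneration_early"].append((chrom, iv.start, iv.end, h_reg))

    tracks = {name: SignalTrack.from_records(rows) if rows else SignalTrack({})
              for name, rows in track_rows.items()}
    return peaks, tracks, region_classes, regions, summits, alloc


def _plant_usage(cfg: SimConfig, rng: np.random.Generator,
                 region_classes, regions, alloc: _LocusAllocator):
    emerging = sorted(r for r, c in region_classes.items() if c == "emerging")
    n_reused = (cfg.n_reused if cfg.n_reused is not None
                else round(cfg.reused_fraction * len(emerging)))
    if n_reused > len(emerging):
        raise ValueError("n_reused exceeds the number of emerging regions")
    reused = set(rng.choice(emerging, size=n_reused, replace=False)) if n_reused else set()

    labels = sorted(REFERENCE_DATASETS)
    ref_regions: Dict[str, List[GenomicInterval]] = {lab: [] for lab in labels}
    for rid in sorted(reused):
        lab = labels[int(rng.integers(len(labels)))]
        ref_regions[lab].append(regions[rid])
    half = cfg.peak_width // 2
    for lab in labels:
        for _ in range(cfg.ref_background_regions):
            chrom, c = alloc.take()
            ref_regions[lab].append(GenomicInterval(chrom, c - half, c + half))
    refs = [
        ReferenceSet(lab, *REFERENCE_DATASETS[lab], regions=RegionSet(ref_regions[lab]))
        for lab in labels
    ]
    return refs, reused


def _plant_chip(cfg: SimConfig, rng: np.random.Generator, region_classes, regions):
    drres = sorted(r for r, c in region_classes.items()
                   if c in ("emerging", "increasing"))
    n_marked = round(cfg.chip_marked_fraction * len(drres))
    marked = sorted(rng.choice(drres, size=n_marked, replace=False)) if n_marked else []
    marked_features: Dict[str, FrozenSet[str]] = {}
    chip_peaks: Dict[str, List[GenomicInterval]] = {f: [] for f in CHIP_FEATURES}
    for rid in marked:
        n_feat = int(rng.integers(1, len(CHIP_FEATURES) + 1))
        feats = tuple(sorted(rng.choice(CHIP_FEATURES, size=n_feat, replace=False)))
        marked_features[rid] = frozenset(feats)
        for f in feats:
            chip_peaks[f].append(regions[rid])
    reg_tracks = {
        f: (SignalTrack.from_records((iv.chrom, iv.start, iv.end, 10.0)
                                     for iv in sorted(chip_peaks[f]))
            if chip_peaks[f] else SignalTrack({}))
        for f in CHIP_FEATURES
    }
    ctl_tracks = {f: SignalTrack({}) for f in CHIP_FEATURES}
    return chip_peaks, reg_tracks, ctl_tracks, marked_features


def _plant_conservation(cfg: SimConfig, rng: np.random.Generator,
                        region_classes, summits, regions):
    conserved = sorted(r for r, c in region_classes.items() if c == "emerging")
    increasing = sorted(r for r, c in region_classes.items() if c == "increasing")
    n_inc = round(cfg.conserved_increasing_fraction * len(increasing))
    if n_inc:
        conserved += sorted(rng.choice(increasing, size=n_inc, replace=False))
    elevated: Dict[str, List[Tuple[int, int]]] = {}
    for rid in conserved:
        iv = regions[rid]
        s = summits[rid]
        elevated.setdefault(iv.chrom, []).append(
            (s - cfg.conservation_halfwidth, s + cfg.conservation_halfwidth)
        )
    rows = []
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        pos = 0
        for lo, hi in sorted(elevated.get(chrom, [])):
            if lo > pos:
                rows.append((chrom, pos, lo, cfg.conservation_background))
            rows.append((chrom, lo, hi, cfg.conservation_peak))
            pos = hi
        if pos < cfg.chrom_length:
            rows.append((chrom, pos, cfg.chrom_length, cfg.conservation_background))
    track = SignalTrack.from_records(rows)

    masks: Dict[str, List[GenomicInterval]] = {
        f"species_{i + 1:02d}": [] for i in range(cfg.n_species_masks)
    }
    names = sorted(masks)
    conserved_set = set(conserved)
    for rid in sorted(regions):
        if region_classes[rid] == "background":
            continue
        if rid in conserved_set:
            n_cover = int(rng.integers(max(2, cfg.n_species_masks - 4),
                                       cfg.n_species_masks + 1))
        else:
            n_cover = int(rng.integers(0, 3))
        if n_cover:
            for sp in rng.choice(names, size=n_cover, replace=False):
                masks[sp].append(regions[rid])
    return track, {sp: RegionSet(ivs) for sp, ivs in masks.items()}


def _plant_orthologs(cfg: SimConfig, rng: np.random.Generator,
                     genes: List[GeneModel], de: Dict[str, Dict[str, str]],
                     core: Set[str]):
    fly_up_any = {g for tp in TIMEPOINTS for g, d in de[tp].items() if d == "up"}
    pairs: List[Tuple[str, str, str]] = []
    up_status: Dict[str, Dict[str, bool]] = {sp: {} for sp in SPECIES}
    prefix = {"zebrafish": "z", "mouse": "m"}
    for g in (gene.gene_id for gene in genes):
        for sp in SPECIES:
            has = g in core or rng.random() < cfg.ortholog_density
            if not has:
                continue
            n_orth = int(rng.integers(1, 3))
            for k in range(n_orth):
                ortho = f"{prefix[sp]}_{g}_{k + 1}"
                pairs.append((g, sp, ortho))
                if g in core:
                    up = True
                elif g in fly_up_any:
                    # non-core fly-up genes may have up orthologs in at most
                    # one species, so the planted core stays exact
                    up = (sp == "zebrafish") and rng.random() < 0.25
                else:
                    up = rng.random() < 0.15
                up_status[sp][ortho] = up
    omap = OrthologMap.from_pairs(pairs)

    tables = {}
    up_sets = {}
    for sp in SPECIES:
        rows = []
        for ortho in sorted(up_status[sp]):
            uninjured = float(rng.uniform(5, 20))
            f = float(rng.uniform(2, 3)) if up_status[sp][ortho] \
                else float(rng.uniform(0.7, 1.3))
            rows.append((ortho, round(uninjured * f, 4), round(uninjured, 4)))
        tables[sp] = pd.DataFrame(rows, columns=["gene_id", "injured", "uninjured"])
        up_sets[sp] = {o for o, u in up_status[sp].items() if u}
    return omap, tables, up_sets


def _fragments(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_fragments
    nf = rng.normal(60, 15, size=n // 2)
    mono = rng.normal(205, 18, size=n // 3)
    other = rng.normal(140, 15, size=n - len(nf) - len(mono))
    lengths = np.concatenate([nf, mono, other])
    return np.clip(np.round(lengths), 20, 500).astype(int)


def simulate_study(config: SimConfig) -> StudyBundle:
    """Generate the full study bundle; deterministic given config.seed."""
    rngs = _layer_rngs(config.seed)
    genes, cluster_truth, cluster_members, excluded = _place_genes(
        config, rngs["genome"])
    expr, de, core = _plant_expression(
        config, rngs["expression"], genes, cluster_members, excluded)
    peaks, tracks, region_classes, regions, summits, alloc = _plant_peaks(
        config, rngs["peaks"])
    refs, reused = _plant_usage(config, rngs["usage"], region_classes, regions, alloc)
    chip_peaks, chip_reg, chip_ctl, marked = _plant_chip(
        config, rngs["chip"], region_classes, regions)
    cons_track, masks = _plant_conservation(
        config, rngs["conservation"], region_classes, summits, regions)
    omap, sp_tables, sp_up = _plant_orthologs(
        config, rngs["orthologs"], genes, de, core)
    frags = _fragments(config, rngs["fragments"])

    truth = SimTruth(
        de=de, clusters=cluster_truth, region_classes=region_classes,
        regions=regions, summits=summits, reused_ids=reused,
        marked_features=marked, core_genes=core,
        fish_up=sp_up["zebrafish"], mouse_up=sp_up["mouse"],
    )
    return StudyBundle(
        config=config, truth=truth, genes=genes, expression=expr,
        atac_peaks=peaks, atac_tracks=tracks, reference_sets=refs,
        chip_peaks=chip_peaks, chip_reg_tracks=chip_reg, chip_ctl_tracks=chip_ctl,
        conservation=cons_track, species_masks=masks, ortholog_map=omap,
        species_expression=sp_tables, fragment_lengths=frags,
    )


def null_study(config: SimConfig) -> StudyBundle:
    """A no-signal study: random DE labels, condition-symmetric peaks.

    Supports type-I-error checks: no clusters are planted (DE labels are a
    uniform draw), no differential regions exist (peak heights differ only
    by symmetric noise below the calling threshold), and species
    up-regulation is independent of the fly labels.
    """
    import dataclasses
    cfg = dataclasses.replace(
        config, n_planted_clusters=0, cluster_genes=0,
        n_emerging=0, n_increasing=0, n_core_genes=0,
    )
    rngs = _layer_rngs(cfg.seed)
    genes, _, _, _ = _place_genes(cfg, rngs["genome"])
    gene_ids = [g.gene_id for g in genes]

    rng = rngs["expression"]
    de: Dict[str, Dict[str, str]] = {tp: {} for tp in TIMEPOINTS}
    n_de = round(cfg.de_fraction * len(gene_ids))
    for tp in TIMEPOINTS:
        chosen = rng.choice(gene_ids, size=n_de, replace=False)
        n_up = round(cfg.de_up_fraction * n_de)
        for i, g in enumerate(chosen):
            de[tp][g] = "up" if i < n_up else "down"
    baseline = np.exp(rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sigma,
                                 size=len(gene_ids)))
    cols = {
        f"{cond}_{tp}_{rep}": baseline * np.exp(
            rng.normal(0, cfg.expression_noise_sigma, size=len(gene_ids)))
        for cond in ("control", "regeneration")
        for tp in TIMEPOINTS
        for rep in range(1, cfg.replicates + 1)
    }
    expr = ExpressionMatrix(pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id")))

    peaks, tracks, region_classes, regions, summits, alloc = _plant_peaks(
        cfg, rngs["peaks"], null=True)
    refs, reused = _plant_usage(cfg, rngs["usage"], region_classes, regions, alloc)
    chip_peaks, chip_reg, chip_ctl, marked = _plant_chip(
        cfg, rngs["chip"], region_classes, regions)
    cons_track, masks = _plant_conservation(
        cfg, rngs["conservation"], region_classes, summits, regions)

    # orthologs and species up-status independent of the fly DE labels
    rng_o = rngs["orthologs"]
    pairs, up_status = [], {sp: {} for sp in SPECIES}
    prefix = {"zebrafish": "z", "mouse": "m"}
    for g in gene_ids:
        for sp in SPECIES:
            if rng_o.random() < cfg.ortholog_density:
                ortho = f"{prefix[sp]}_{g}_1"
                pairs.append((g, sp, ortho))
                up_status[sp][ortho] = rng_o.random() < 0.3
    omap = OrthologMap.from_pairs(pairs)
    tables, up_sets = {}, {}
    for sp in SPECIES:
        rows = []
        for ortho in sorted(up_status[sp]):
            uninjured = float(rng_o.uniform(5, 20))
            f = float(rng_o.uniform(2, 3)) if up_status[sp][ortho] \
                else float(rng_o.uniform(0.7, 1.3))
            rows.append((ortho, round(uninjured * f, 4), round(uninjured, 4)))
        tables[sp] = pd.DataFrame(rows, columns=["gene_id", "injured", "uninjured"])
        up_sets[sp] = {o for o, u in up_status[sp].items() if u}

    truth = SimTruth(
        de=de, clusters=[], region_classes=region_classes, regions=regions,
        summits=summits, reused_ids=reused, marked_features=marked,
        core_genes=set(), fish_up=up_sets["zebrafish"], mouse_up=up_sets["mouse"],
    )
    return StudyBundle(
        config=cfg, truth=truth, genes=genes, expression=expr,
        atac_peaks=peaks, atac_tracks=tracks, reference_sets=refs,
        chip_peaks=chip_peaks, chip_reg_tracks=chip_reg, chip_ctl_tracks=chip_ctl,
        conservation=cons_track, species_masks=masks, ortholog_map=omap,
        species_expression=tables, fragment_lengths=_fragments(cfg, rngs["fragments"]),
    )


def load_bundle(indir) -> StudyBundle:
    """Re-read a bundle written by :meth:`StudyBundle.write`."""
    ind = Path(indir)
    genes = dio.read_gtf(ind / "genes.gtf")
    expr = ExpressionMatrix.read_tsv(ind / "expression.tsv")
    peaks: Dict[Tuple, List[Peak]] = {}
    for path in sorted((ind / "peaks").glob("atac_*.bed")):
        parts = path.stem.split("_")[1:]
        if parts[0] == "L3":
            key: Tuple = ("L3", int(parts[1]))
        else:
            key = (parts[0], parts[1], int(parts[2]))
        peaks[key] = dio.read_peaks(path)
    tracks = {
        p.stem.replace("atac_", ""): dio.read_bedgraph(p)
        for p in sorted((ind / "tracks").glob("atac_*.bedgraph"))
    }
    manifest = pd.read_csv(ind / "refs/manifest.tsv", sep="\t")
    refs = [
        ReferenceSet(row.label, row.stage, row.tissue,
                     RegionSet(dio.read_bed(ind / row.path)))
        for row in manifest.itertuples()
    ]
    chip_peaks, chip_reg, chip_ctl = {}, {}, {}
    for f in CHIP_FEATURES:
        chip_peaks[f] = dio.read_bed(ind / f"chip/{f}_regeneration_peaks.bed")
        chip_reg[f] = dio.read_bedgraph(ind / f"chip/{f}_regeneration.bedgraph")
        chip_ctl[f] = dio.read_bedgraph(ind / f"chip/{f}_control.bedgraph")
    cons = dio.read_bedgraph(ind / "conservation.bedgraph")
    masks = {
        row.species: RegionSet(dio.read_bed(ind / row.path))
        for row in pd.read_csv(ind / "masks/manifest.tsv", sep="\t").itertuples()
    }
    omap = OrthologMap.read_tsv(ind / "orthologs.tsv")
    sp_tables = {
        sp: pd.read_csv(ind / f"expression_{sp}.tsv", sep="\t") for sp in SPECIES
    }
    frags = pd.read_csv(ind / "fragments.tsv", sep="\t").length.values

    de_df = pd.read_csv(ind / "truth/de_genes.tsv", sep="\t")
    de = {tp: {} for tp in TIMEPOINTS}
    for row in de_df.itertuples():
        de[row.timepoint][row.gene_id] = row.direction
    cl_df = pd.read_csv(ind / "truth/clusters.tsv", sep="\t")
    clusters = [
        {"chrom": r.chrom, "members": tuple(r.members.split(",")),
         "timepoint": r.timepoint, "direction": r.direction}
        for r in cl_df.itertuples()
    ]
    reg_df = pd.read_csv(ind / "truth/regions.tsv", sep="\t",
                         keep_default_na=False)
    region_classes, regions, summits, reused, marked = {}, {}, {}, set(), {}
    for _, r in reg_df.iterrows():
        rid = r["region_id"]
        region_classes[rid] = r["class"]
        regions[rid] = GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]))
        summits[rid] = int(r["summit"])
        if r["usage"] == "reused":
            reused.add(rid)
        if r["marked_features"]:
            marked[rid] = frozenset(r["marked_features"].split(","))
    core = set(pd.read_csv(ind / "truth/core_genes.tsv", sep="\t").gene_id)

    fish_up = {
        r.gene_id for r in sp_tables["zebrafish"].itertuples()
        if (r.injured + 0.01) / (r.uninjured + 0.01) >= 1.5
    }
    mouse_up = {
        r.gene_id for r in sp_tables["mouse"].itertuples()
        if (r.injured + 0.01) / (r.uninjured + 0.01) >= 1.5
    }
    truth = SimTruth(
        de=de, clusters=clusters, region_classes=region_classes, regions=regions,
        summits=summits, reused_ids=reused, marked_features=marked,
        core_genes=core, fish_up=fish_up, mouse_up=mouse_up,
    )
    # config cannot be fully recovered from disk; keep defaults with the
    # counts implied by the truth table
    cfg = SimConfig()
    return StudyBundle(
        config=cfg, truth=truth, genes=genes, expression=expr,
        atac_peaks=peaks, atac_tracks=tracks, reference_sets=refs,
        chip_peaks=chip_peaks, chip_reg_tracks=chip_reg, chip_ctl_tracks=chip_ctl,
        conservation=cons, species_masks=masks, ortholog_map=omap,
        species_expression=sp_tables, fragment_lengths=frags,
    )
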
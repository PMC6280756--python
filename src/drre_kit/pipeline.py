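"""End-to-end orchestration: study bundle in, stage outputs + manifest out.

Stages run in dependency order (de -> clusters -> atac -> annotate -> usage
-> features -> conserve -> core).  Stage selection controls which outputs
are written; upstream results a selected stage needs are computed in memory
either way.  All inputs and parameters are validated before the first stage
runs, and the manifest records, for every output file, its SHA-256 checksum
and the full parameter set, so identical config + seed reruns are
byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .accessibility import (classify_drres, concordant_peaks, consensus_regions,
                            differential_accessibility)
from .annotation import GeneIndex, annotate_drres, annotation_spectrum
from .clustering import (cluster_coregulation, find_clusters, find_hotspots,
                         gene_positions)
from .conservation import anchor_profile, classify_usage_all, species_conservation
from .cross_species import (call_up_species, core_genes,
                            ortholog_enrichment_test)
from .enhancers import FEATURES, call_activity_all
from .expression import TIMEPOINTS, call_de
from .intervals import RegionSet
from .simulate import StudyBundle

log = logging.getLogger("drre_kit")

STAGES = ("de", "clusters", "atac", "annotate", "usage", "features",
          "conserve", "core")

#: every fold-change threshold and window in the analysis, by name
DEFAULT_PARAMS: Dict[str, float] = {
    "theta_de": 1.7,            # DE fold-change threshold
    "theta_acc": 1.5,           # differential-accessibility fold threshold
    "theta_species": 1.5,       # species up-regulation fold threshold
    "eps": 0.01,                # pseudocount for all ratios / log profiles
    "cp_window": 100,           # core-promoter window, bp around the TSS
    "prox_window": 2000,        # proximal window, bp around the TSS
    "feature_window": 500,      # ChIP marking window, bp around the ATAC peak
    "cluster_window": 30000,    # gene-cluster sliding window, bp
    "cluster_offset": 10000,    # window advance, bp
    "cluster_min_genes": 3,     # minimum DE genes per cluster window
    "cluster_alpha": 0.05,      # window p/q threshold (BH)
    "hotspot_window": 1000000,  # hotspot window, bp
    "hotspot_min_clusters": 2,
    "profile_flank": 500,       # summit-anchored profile half-width, bp
    "tau": 0.5,                 # species-presence aligned fraction
    "n_permutations": 10000,    # ortholog enrichment null draws
}


class PipelineError(RuntimeError):
    """Raised on invalid configuration or missing inputs, naming the stage."""


def _validate(bundle: StudyBundle, params: Dict, stages: Sequence[str]) -> None:
    bad = set(stages) - set(STAGES)
    if bad:
        raise PipelineError(f"unknown stages: {sorted(bad)}")
    for key in ("theta_de", "theta_acc", "theta_species"):
        if params[key] <= 1:
            raise PipelineError(f"parameter {key} must exceed 1")
    for key in ("cp_window", "prox_window", "feature_window", "cluster_window",
                "cluster_offset", "hotspot_window", "profile_flank"):
        if params[key] <= 0:
            raise PipelineError(f"parameter {key} must be positive")
    if not 0 < params["cluster_alpha"] < 1:
        raise PipelineError("cluster_alpha must be in (0, 1)")
    need_atac = {"atac", "annotate", "usage", "features", "conserve"} & set(stages)
    if need_atac:
        for key in (("control", "early", 1), ("control", "early", 2),
                    ("regeneration", "early", 1), ("regeneration", "early", 2)):
            if key not in bundle.atac_peaks:
                raise PipelineError(f"stage atac: missing peak set {key}")
        if ("L3", 1) not in bundle.atac_peaks or ("L3", 2) not in bundle.atac_peaks:
            raise PipelineError("stage atac: missing L3 peak sets (DRRE "
                                "classification requires the L3 baseline)")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _merged_params(params: Optional[Dict]) -> Dict:
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise PipelineError(f"unknown parameters: {sorted(unknown)}")
        p.update(params)
    return p


def discover_drres(bundle: StudyBundle, params: Optional[Dict] = None):
    """In-memory DRRE discovery on the early damage timepoint.

    Replicate concordance, differential accessibility against the matched
    control, emerging/increasing classification against control and L3 open
    sets, annotation, usage, and activity calls — the same composition
    ``run_all`` writes to ``drres.tsv``.
    """
    p = _merged_params(params)
    _validate(bundle, p, ["atac"])
    ctl = concordant_peaks(bundle.atac_peaks[("control", "early", 1)],
                           bundle.atac_peaks[("control", "early", 2)])
    reg = concordant_peaks(bundle.atac_peaks[("regeneration", "early", 1)],
                           bundle.atac_peaks[("regeneration", "early", 2)])
    l3 = concordant_peaks(bundle.atac_peaks[("L3", 1)],
                          bundle.atac_peaks[("L3", 2)])
    diffs = differential_accessibility(
        ctl, reg,
        bundle.atac_tracks.get("control_early"),
        bundle.atac_tracks.get("regeneration_early"),
        theta=p["theta_acc"], eps=p["eps"], timepoint="early",
    )
    drres = classify_drres(diffs, RegionSet(consensus_regions([ctl])),
                           RegionSet(consensus_regions([l3])))
    annotate_drres(drres, GeneIndex(bundle.genes),
                   cp_window=int(p["cp_window"]),
                   prox_window=int(p["prox_window"]))
    classify_usage_all(drres, bundle.reference_sets)
    call_activity_all(drres, bundle.chip_peaks,
                      bundle.chip_reg_tracks, bundle.chip_ctl_tracks,
                      window=int(p["feature_window"]))
    return drres


def discover_clusters(bundle: StudyBundle, params: Optional[Dict] = None):
    """DE gene clusters per (timepoint, direction), in memory."""
    p = _merged_params(params)
    positions = gene_positions(bundle.genes)
    out = {}
    for tp in TIMEPOINTS:
        table = call_de(bundle.expression, tp, theta=p["theta_de"],
                        eps=p["eps"])
        for direction in ("up", "down"):
            de_set = set(table.loc[table.direction == direction, "gene_id"])
            out[(tp, direction)] = find_clusters(
                positions, de_set, direction,
                window=int(p["cluster_window"]),
                offset=int(p["cluster_offset"]),
                min_genes=int(p["cluster_min_genes"]),
                alpha=p["cluster_alpha"],
            )
    return out


def run_all(
    bundle: StudyBundle,
    out_dir,
    seed: int = 0,
    params: Optional[Dict] = None,
    stages: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Run the selected stages on a study bundle; returns the manifest."""
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise PipelineError(f"unknown parameters: {sorted(unknown)}")
        p.update(params)
    stages = list(stages) if stages is not None else list(STAGES)
    _validate(bundle, p, stages)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    param_json = json.dumps(p, sort_keys=True)
    manifest_rows: List[Dict] = []

    def emit(stage: str, name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False)
        manifest_rows.append({
            "stage": stage, "output": name, "sha256": _sha256(path),
            "rows": len(df), "seed": seed, "version": __version__,
            "params": param_json,
        })
        log.info("stage %s: wrote %s (%d records)", stage, name, len(df))

    # ---- de ------------------------------------------------------------
    de_tables = {
        tp: call_de(bundle.expression, tp, theta=p["theta_de"], eps=p["eps"])
        for tp in TIMEPOINTS
    }
    if "de" in stages:
        for tp, table in de_tables.items():
            emit("de", f"de_{tp}.tsv", table)

    # ---- clusters ------------------------------------------------------
    if "clusters" in stages or "core" in stages:
        positions = gene_positions(bundle.genes)
    if "clusters" in stages:
        cluster_rows, hotspot_rows = [], []
        for tp in TIMEPOINTS:
            for direction in ("up", "down"):
                de_set = set(de_tables[tp].loc[
                    de_tables[tp].direction == direction, "gene_id"])
                clusters = find_clusters(
                    positions, de_set, direction,
                    window=int(p["cluster_window"]),
                    offset=int(p["cluster_offset"]),
                    min_genes=int(p["cluster_min_genes"]),
                    alpha=p["cluster_alpha"],
                )
                for c in clusters:
                    coreg = cluster_coregulation(c, bundle.expression, eps=p["eps"])
                    cluster_rows.append({
                        "timepoint": tp, "cluster_id": c.cluster_id,
                        "chrom": c.interval.chrom, "start": c.interval.start,
                        "end": c.interval.end, "direction": c.direction,
                        "n_members": len(c.members),
                        "members": ",".join(c.members),
                        "p_value": c.p_value, "q_value": c.q_value,
                        "mean_pair_r": coreg["mean_r"],
                    })
                for h in find_hotspots(clusters,
                                       window=int(p["hotspot_window"]),
                                       min_clusters=int(p["hotspot_min_clusters"])):
                    hotspot_rows.append({
                        "timepoint": tp, "direction": direction,
                        "chrom": h.interval.chrom, "start": h.interval.start,
                        "end": h.interval.end,
                        "clusters": ",".join(h.cluster_ids),
                    })
        cluster_cols = ["timepoint", "cluster_id", "chrom", "start", "end",
                        "direction", "n_members", "members", "p_value",
                        "q_value", "mean_pair_r"]
        hotspot_cols = ["timepoint", "direction", "chrom", "start", "end",
                        "clusters"]
        emit("clusters", "clusters.tsv",
             pd.DataFrame(cluster_rows, columns=cluster_cols))
        emit("clusters", "hotspots.tsv",
             pd.DataFrame(hotspot_rows, columns=hotspot_cols))

    # ---- atac / classify ----------------------------------------------
    drres = None
    need_atac = {"atac", "annotate", "usage", "features", "conserve"} & set(stages)
    if need_atac:
        drres = discover_drres(bundle, params)

    def drre_frame() -> pd.DataFrame:
        rows = []
        for d in drres:
            rows.append({
                "chrom": d.interval.chrom, "start": d.interval.start,
                "end": d.interval.end, "summit": d.summit,
                "class": d.drre_class, "mode": d.region.mode,
                "fold": "" if d.region.fold is None else round(d.region.fold, 4),
                "prior_openness": d.prior_openness,
                "category": d.annotation.category,
                "gene": d.annotation.gene_id or "",
                "distance_to_tss": d.annotation.distance_to_tss,
                "usage": d.usage.usage if d.drre_class == "emerging" else "",
                "supporting_datasets": ",".join(d.usage.supporting_datasets),
                "activity": d.activity.activity,
                **{f: dict(d.activity.statuses)[f] for f in FEATURES},
            })
        return pd.DataFrame(rows)

    if "atac" in stages:
        emit("atac", "drres.tsv", drre_frame())
    if "annotate" in stages:
        emit("annotate", "annotation_spectrum.tsv", annotation_spectrum(drres))
    if "usage" in stages:
        emerging = [d for d in drres if d.drre_class == "emerging"]
        n_reused = sum(d.usage.usage == "reused" for d in emerging)
        usage_df = pd.DataFrame([{
            "n_emerging": len(emerging), "n_reused": n_reused,
            "n_novel": len(emerging) - n_reused,
            "percent_reused": (100.0 * n_reused / len(emerging)) if emerging else "",
            "percent_novel": (100.0 * (len(emerging) - n_reused) / len(emerging))
                             if emerging else "",
        }])
        emit("usage", "usage_summary.tsv", usage_df)
    if "features" in stages:
        counts = pd.DataFrame([{
            "n_drres": len(drres),
            "n_presence": sum(d.activity.activity == "presence" for d in drres),
            "n_absence": sum(d.activity.activity == "absence" for d in drres),
        }])
        emit("features", "activity_summary.tsv", counts)

    # ---- conserve ------------------------------------------------------
    if "conserve" in stages:
        anchors = [(d.interval.chrom, d.summit) for d in drres]
        profile = anchor_profile(anchors, bundle.conservation,
                                 flank=int(p["profile_flank"]))
        emit("conserve", "conservation_profile.tsv", profile)
        rows = []
        for d in drres:
            n_sp, pct = species_conservation(d, bundle.species_masks, tau=p["tau"])
            rows.append({
                "chrom": d.interval.chrom, "start": d.interval.start,
                "end": d.interval.end, "class": d.drre_class,
                "n_species": n_sp, "percent_aligned": round(pct, 3),
            })
        emit("conserve", "species_conservation.tsv", pd.DataFrame(rows))

    # ---- core ----------------------------------------------------------
    if "core" in stages:
        up = {
            tp: set(de_tables[tp].loc[de_tables[tp].direction == "up", "gene_id"])
            for tp in TIMEPOINTS
        }
        sp_up = {}
        for sp, table in bundle.species_expression.items():
            injured = dict(zip(table.gene_id, table.injured))
            uninjured = dict(zip(table.gene_id, table.uninjured))
            sp_up[sp] = call_up_species(injured, uninjured,
                                        theta=p["theta_species"], eps=p["eps"])
        core = core_genes(up["early"], up["mid"],
                          sp_up["zebrafish"], sp_up["mouse"], bundle.ortholog_map)
        core_rows = [{
            "gene_id": g,
            "zebrafish_orthologs": ",".join(sorted(core.support[g]["zebrafish"])),
            "mouse_orthologs": ",".join(sorted(core.support[g]["mouse"])),
        } for g in sorted(core.genes)]
        emit("core", "core_genes.tsv", pd.DataFrame(core_rows))

        background = sorted(bundle.ortholog_map.fly_genes)
        indicator = {
            g: bool(bundle.ortholog_map.orthologs(g, "zebrafish") & sp_up["zebrafish"]
                    or bundle.ortholog_map.orthologs(g, "mouse") & sp_up["mouse"])
            for g in background
        }
        fly_up_both = (up["early"] | up["mid"]) & set(background)
        enrich = ortholog_enrichment_test(
            fly_up_both, background, indicator,
            n_permutations=int(p["n_permutations"]), seed=seed,
        )
        emit("core", "ortholog_enrichment.tsv", pd.DataFrame([enrich]))

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest
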
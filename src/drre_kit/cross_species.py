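"""Cross-species regeneration-core analysis and the zebrafish DRRE arm.

Fly genes are mapped to zebrafish and mouse orthologs in a fly-oriented,
many-to-many way.  Species up-regulation is a 1.5-fold injured/uninjured
rule.  The regeneration core is the set of fly genes up-regulated after
damage (early and/or mid) with at least one up-regulated ortholog in
zebrafish heart regeneration AND at least one in mouse liver regeneration;
the core is counted in fly genes, never in ortholog pairs.

Whether fly regeneration genes are unusually likely to have regeneration
orthologs is assessed with a seeded permutation test (same-size uniform
draws from the background without replacement); the exact null is
hypergeometric, which serves as an independent cross-check.

The zebrafish chromatin arm reuses the fly machinery: emerging = H3.3 peaks
exclusively called in regeneration, increasing = called in both samples and
at least 1.5-fold higher when injured; annotation uses a 0.5-kb CP window
and reusage is overlap with embryonic open chromatin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .accessibility import (DRRE, Peak, classify_drres,
                            consensus_regions, differential_accessibility)
from .annotation import GeneIndex, annotate_drres
from .conservation import ReferenceSet, classify_usage_all
from .genes import GeneModel
from .intervals import RegionSet
from .signal import SignalTrack

SPECIES = ("zebrafish", "mouse")

__all__ = ["OrthologMap", "CoreGeneSet", "ortholog_class", "call_up_species",
           "core_genes", "ortholog_enrichment_test", "zebrafish_drre"]


class OrthologMap:
    """Fly gene -> ortholog id sets per species (many-to-many)."""

    def __init__(self, mapping: Mapping[str, Mapping[str, Set[str]]]):
        self._map: Dict[str, Dict[str, Set[str]]] = {
            g: {sp: set(m.get(sp, ())) for sp in SPECIES}
            for g, m in mapping.items()
        }

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str, str]]) -> "OrthologMap":
        """Build from (fly_gene, species, ortholog_gene) rows."""
        mapping: Dict[str, Dict[str, Set[str]]] = {}
        for fly, species, ortho in pairs:
            if species not in SPECIES:
                raise ValueError(f"unknown species {species!r}")
            mapping.setdefault(fly, {sp: set() for sp in SPECIES})[species].add(ortho)
        return cls(mapping)

    @classmethod
    def read_tsv(cls, path: Union[str, Path]) -> "OrthologMap":
        df = pd.read_csv(path, sep="\t")
        return cls.from_pairs(df[["fly_gene", "species", "ortholog_gene"]].itertuples(index=False))

    def to_tsv(self, path: Union[str, Path]) -> None:
        rows = [
            (fly, sp, o)
            for fly in sorted(self._map)
            for sp in SPECIES
            for o in sorted(self._map[fly][sp])
        ]
        pd.DataFrame(rows, columns=["fly_gene", "species", "ortholog_gene"]) \
            .to_csv(path, sep="\t", index=False)

    def orthologs(self, gene: str, species: str) -> Set[str]:
        return set(self._map.get(gene, {}).get(species, ()))

    @property
    def fly_genes(self) -> Set[str]:
        return set(self._map)


@dataclass(frozen=True)
class CoreGeneSet:
    genes: frozenset
    support: Mapping[str, Dict[str, Set[str]]]  # gene -> species -> up orthologs

    def __len__(self) -> int:
        return len(self.genes)


def ortholog_class(gene: str, omap: OrthologMap) -> str:
    """none / zebrafish_only / mouse_only / both."""
    z = bool(omap.orthologs(gene, "zebrafish"))
    m = bool(omap.orthologs(gene, "mouse"))
    if z and m:
        return "both"
    if z:
        return "zebrafish_only"
    if m:
        return "mouse_only"
    return "none"


def call_up_species(
    injured: Mapping[str, float],
    uninjured: Mapping[str, float],
    theta: float = 1.5,
    eps: float = 0.01,
) -> Set[str]:
    """Genes with (injured + eps) / (uninjured + eps) >= theta."""
    if set(injured) != set(uninjured):
        raise ValueError("injured and uninjured tables cover different genes")
    return {
        g for g in injured
        if (injured[g] + eps) / (uninjured[g] + eps) >= theta
    }


def core_genes(
    fly_up_early: Set[str],
    fly_up_mid: Set[str],
    fish_up: Set[str],
    mouse_up: Set[str],
    omap: OrthologMap,
) -> CoreGeneSet:
    """Fly-oriented regeneration core (see module docstring)."""
    members = {}
    for gene in fly_up_early | fly_up_mid:
        z_hits = omap.orthologs(gene, "zebrafish") & fish_up
        m_hits = omap.orthologs(gene, "mouse") & mouse_up
        if z_hits and m_hits:
            members[gene] = {"zebrafish": z_hits, "mouse": m_hits}
    return CoreGeneSet(frozenset(members), members)


def ortholog_enrichment_test(
    fly_up: Set[str],
    background: Sequence[str],
    has_up_ortholog: Mapping[str, bool],
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """Permutation p-value for enrichment of regeneration orthologs.

    observed = number of fly-up genes whose indicator is true; the null
    draws |fly_up| genes uniformly without replacement from the background;
    p = (1 + #{draws >= observed}) / (B + 1).
    """
    background = list(background)
    if not set(fly_up) <= set(background):
        raise ValueError("fly_up must be a subset of the background")
    if len(fly_up) > len(background):
        raise ValueError("fly_up larger than background")
    if rng is None:
        rng = np.random.default_rng(seed)
    indicator = np.array([bool(has_up_ortholog.get(g, False)) for g in background])
    observed = int(sum(indicator[i] for i, g in enumerate(background) if g in fly_up))
    k, n = len(fly_up), len(background)
    if k == 0:
        return {"observed": 0, "expected": 0.0, "p_value": 1.0,
                "n_permutations": n_permutations}
    # uniform without-replacement draws, vectorized via random keys
    keys = rng.random((n_permutations, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    counts = indicator[idx].sum(axis=1)
    p = (1 + int(np.sum(counts >= observed))) / (n_permutations + 1)
    return {
        "observed": observed,
        "expected": float(k * indicator.mean()),
        "p_value": float(p),
        "n_permutations": n_permutations,
    }


def zebrafish_drre(
    uninjured_peaks: Sequence[Peak],
    injured_peaks: Sequence[Peak],
    uninjured_track: Optional[SignalTrack],
    injured_track: Optional[SignalTrack],
    genes: Union[GeneIndex, Iterable[GeneModel]],
    embryo_open: RegionSet,
    theta: float = 1.5,
    cp_window: int = 500,
    prox_window: int = 2000,
) -> List[DRRE]:
    """Zebrafish DRRE classification with embryo reusage.

    Inputs are concordant peak sets.  With no L3 baseline in this system,
    emerging means exclusively called in regeneration.
    """
    diffs = differential_accessibility(
        uninjured_peaks, injured_peaks, uninjured_track, injured_track,
        theta=theta,
    )
    uninjured_open = RegionSet(p.interval for p in uninjured_peaks)
    drres = classify_drres(diffs, uninjured_open, RegionSet())
    annotate_drres(drres, genes, cp_window=cp_window, prox_window=prox_window)
    embryo_ref = ReferenceSet("embryo_24hpf", "embryo", "whole", embryo_open)
    classify_usage_all(drres, [embryo_ref])
    return drres
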
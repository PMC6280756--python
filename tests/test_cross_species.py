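import numpy as np
import pytest
from scipy.stats import hypergeom

from drre_kit.cross_species import (OrthologMap, call_up_species, core_genes,
                                    ortholog_class, ortholog_enrichment_test)


@pytest.fixture
def omap():
    return OrthologMap.from_pairs([
        ("fly1", "zebrafish", "z1"),
        ("fly1", "zebrafish", "z1b"),
        ("fly1", "mouse", "m1"),
        ("fly2", "zebrafish", "z2"),
        ("fly3", "mouse", "m3"),
    ])


def test_ortholog_class(omap):
    assert ortholog_class("fly1", omap) == "both"
    assert ortholog_class("fly2", omap) == "zebrafish_only"
    assert ortholog_class("fly3", omap) == "mouse_only"
    assert ortholog_class("fly9", omap) == "none"


def test_call_up_species_threshold():
    injured = {"a": 3.0, "b": 1.49, "c": 1.5}
    uninjured = {"a": 1.0, "b": 1.0, "c": 1.0}
    # 1.5-fold rule with eps 0.01: c is right at the boundary after eps
    up = call_up_species(injured, uninjured)
    assert "a" in up and "b" not in up
    with pytest.raises(ValueError):
        call_up_species({"a": 1.0}, {"b": 1.0})


def test_core_requires_both_species(omap):
    fly_up = {"fly1", "fly2", "fly3"}
    core = core_genes(fly_up, set(), {"z1", "z2"}, {"m1", "m3"}, omap)
    # fly2 lacks a mouse ortholog, fly3 lacks an up zebrafish ortholog
    assert core.genes == frozenset({"fly1"})
    assert core.support["fly1"]["zebrafish"] == {"z1"}
    assert core.support["fly1"]["mouse"] == {"m1"}


def test_core_counts_fly_genes_once(omap):
    # fly1 has two up zebrafish orthologs but is one core gene
    core = core_genes({"fly1"}, set(), {"z1", "z1b"}, {"m1"}, omap)
    assert len(core) == 1


def test_core_monotone_in_species_up_sets(omap):
    small = core_genes({"fly1", "fly2"}, set(), {"z1"}, {"m1"}, omap)
    large = core_genes({"fly1", "fly2"}, set(), {"z1", "z2"}, {"m1"}, omap)
    assert small.genes <= large.genes


def test_core_union_of_timepoints(omap):
    via_mid = core_genes(set(), {"fly1"}, {"z1"}, {"m1"}, omap)
    assert via_mid.genes == frozenset({"fly1"})


def test_enrichment_p_matches_hypergeometric_tail():
    """With many permutations the p-value approaches the exact tail."""
    rng_bg = [f"g{i}" for i in range(60)]
    ind = {g: i < 20 for i, g in enumerate(rng_bg)}  # K = 20 of N = 60
    fly_up = set(rng_bg[:10]) | set(rng_bg[30:35])   # k = 15, observed = 10
    res = ortholog_enrichment_test(fly_up, rng_bg, ind,
                                   n_permutations=40_000, seed=4)
    exact = hypergeom.sf(res["observed"] - 1, 60, 20, 15)
    assert res["observed"] == 10
    assert res["expected"] == pytest.approx(15 * 20 / 60)
    assert res["p_value"] == pytest.approx(exact, abs=0.01)


def test_enrichment_validation():
    with pytest.raises(ValueError):
        ortholog_enrichment_test({"x"}, ["a", "b"], {}, seed=0)


def test_enrichment_deterministic_given_seed():
    bg = [f"g{i}" for i in range(40)]
    ind = {g: i % 3 == 0 for i, g in enumerate(bg)}
    a = ortholog_enrichment_test(set(bg[:8]), bg, ind, 2000, seed=9)
    b = ortholog_enrichment_test(set(bg[:8]), bg, ind, 2000, seed=9)
    assert a == b


def test_ortholog_map_round_trip(tmp_path, omap):
    path = tmp_path / "omap.tsv"
    omap.to_tsv(path)
    again = OrthologMap.read_tsv(path)
    for g in omap.fly_genes:
        for sp in ("zebrafish", "mouse"):
            assert again.orthologs(g, sp) == omap.orthologs(g, sp)


def test_zebrafish_arm_classes():
    from drre_kit.accessibility import Peak
    from drre_kit.cross_species import zebrafish_drre
    from drre_kit.genes import GeneModel
    from drre_kit.intervals import GenomicInterval, RegionSet

    def peak(s, e, h):
        return Peak(GenomicInterval("z1", s, e), (s + e) // 2, h)

    uninjured = [peak(10_000, 10_400, 5.0)]
    injured = [peak(10_000, 10_400, 10.0),   # 2-fold up -> increasing
               peak(50_000, 50_400, 8.0)]    # injured-only -> emerging
    gene = GeneModel.from_exon_lists(
        "zgene", "z1", "+", [[GenomicInterval("z1", 10_100, 10_600)]])
    embryo = RegionSet([GenomicInterval("z1", 49_900, 50_500)])
    drres = zebrafish_drre(uninjured, injured, None, None, [gene], embryo)
    by_start = {d.interval.start: d for d in drres}
    assert by_start[10_000].drre_class == "increasing"
    assert by_start[50_000].drre_class == "emerging"
    # 500 bp CP window: summit 10_200 is within 500 bp of TSS 10_100
    assert by_start[10_000].annotation.category == "CP"
    assert by_start[50_000].usage.usage == "reused"
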
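import numpy as np
import pandas as pd
import pytest

from drre_kit.clustering import find_clusters, find_hotspots, gene_positions
from drre_kit.genes import GeneModel
from drre_kit.intervals import GenomicInterval


def positions_frame(tss_by_gene, chrom="chr1"):
    return pd.DataFrame({
        "gene_id": list(tss_by_gene),
        "chrom": chrom,
        "tss": [tss_by_gene[g] for g in tss_by_gene],
    })


def test_gene_positions_uses_tss():
    g = GeneModel.from_exon_lists(
        "g1", "chr1", "-",
        [[GenomicInterval("chr1", 100, 200)]])
    df = gene_positions([g])
    assert df.loc[0, "tss"] == 199


def test_planted_run_is_recovered():
    # 40 scattered genes plus a tight run of 4 DE genes
    rng = np.random.default_rng(5)
    tss = {f"bg{i}": int(p) for i, p in
           enumerate(sorted(rng.integers(0, 2_000_000, 40)))}
    tss.update({f"hit{i}": 1_000_000 + i * 4000 for i in range(4)})
    de = {f"hit{i}" for i in range(4)}
    clusters = find_clusters(positions_frame(tss), de, "up")
    assert len(clusters) == 1
    assert set(clusters[0].members) == de
    assert clusters[0].direction == "up"
    assert clusters[0].p_value <= 0.05 and clusters[0].q_value <= 0.05
    # interval spans member TSSs
    assert clusters[0].interval.start == 1_000_000
    assert clusters[0].interval.end == 1_012_001


def test_spread_de_genes_do_not_cluster():
    tss = {f"g{i}": i * 100_000 for i in range(40)}
    de = {"g0", "g10", "g20", "g30"}  # 100 kb apart, window is 30 kb
    assert find_clusters(positions_frame(tss), de, "up") == []


def test_min_genes_threshold():
    tss = {f"g{i}": i * 50_000 for i in range(40)}
    tss.update({"a": 900_000, "b": 905_000})
    clusters = find_clusters(positions_frame(tss), {"a", "b"}, "up",
                             min_genes=3)
    assert clusters == []


def test_empty_de_set():
    tss = {f"g{i}": i * 1000 for i in range(10)}
    assert find_clusters(positions_frame(tss), set(), "up") == []


def test_hotspots_require_min_clusters():
    from drre_kit.clustering import GeneCluster

    def cl(cid, start):
        return GeneCluster(cid, GenomicInterval("chr1", start, start + 10_000),
                           ("x",), "up", 0.01, 0.01)

    near = [cl("c1", 0), cl("c2", 500_000)]
    far = [cl("c3", 5_000_000)]
    hot = find_hotspots(near + far, window=1_000_000, min_clusters=2)
    assert len(hot) == 1
    assert set(hot[0].cluster_ids) == {"c1", "c2"}
    assert find_hotspots(far, window=1_000_000, min_clusters=2) == []


def test_planted_bundle_clusters(bundle, pipeline_out):
    out, _ = pipeline_out
    found = pd.read_csv(out / "clusters.tsv", sep="\t")
    truth = bundle.truth.clusters
    assert len(found) == len(truth)
    truth_sets = [set(t["members"]) for t in truth]
    for members in found.members:
        got = set(members.split(","))
        assert max(len(got & t) / len(got | t) for t in truth_sets) >= 0.8
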
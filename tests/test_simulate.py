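import numpy as np
import pandas as pd
import pytest

from drre_kit.simulate import (SimConfig, load_bundle, null_study,
                               simulate_study)


def test_deterministic_given_seed(tmp_path):
    a = simulate_study(SimConfig(seed=21))
    b = simulate_study(SimConfig(seed=21))
    a.write(tmp_path / "a")
    b.write(tmp_path / "b")
    for rel in sorted(p.relative_to(tmp_path / "a")
                      for p in (tmp_path / "a").rglob("*") if p.is_file()):
        assert (tmp_path / "a" / rel).read_bytes() == \
            (tmp_path / "b" / rel).read_bytes(), rel


def test_different_seeds_differ():
    a = simulate_study(SimConfig(seed=1))
    b = simulate_study(SimConfig(seed=2))
    assert a.truth.core_genes != b.truth.core_genes or \
        a.truth.regions != b.truth.regions


def test_truth_counts_match_config(bundle):
    cfg = bundle.config
    classes = bundle.truth.region_classes
    counts = pd.Series(classes).value_counts()
    assert counts["emerging"] == cfg.n_emerging
    assert counts["increasing"] == cfg.n_increasing
    assert counts["background"] == cfg.n_background_peaks
    assert len(bundle.truth.clusters) == cfg.n_planted_clusters
    assert all(len(c["members"]) == cfg.cluster_genes
               for c in bundle.truth.clusters)
    assert len(bundle.truth.core_genes) == cfg.n_core_genes
    assert len(bundle.genes) == cfg.n_genes
    assert len(bundle.fragment_lengths) == cfg.n_fragments


def test_reused_count_override():
    b = simulate_study(SimConfig(seed=5, n_emerging=40, n_reused=13))
    assert len(b.truth.reused_ids) == 13


def test_bundle_round_trip(tmp_path, bundle):
    bundle.write(tmp_path / "bundle")
    again = load_bundle(tmp_path / "bundle")
    assert {g.gene_id for g in again.genes} == \
        {g.gene_id for g in bundle.genes}
    pd.testing.assert_frame_equal(again.expression.df, bundle.expression.df,
                                  check_exact=False)
    assert again.truth.region_classes == bundle.truth.region_classes
    assert again.truth.reused_ids == bundle.truth.reused_ids
    assert again.truth.core_genes == bundle.truth.core_genes
    for key in bundle.atac_peaks:
        assert sorted(p.interval for p in again.atac_peaks[key]) == \
            sorted(p.interval for p in bundle.atac_peaks[key])


def test_null_study_has_no_planted_structure():
    nb = null_study(SimConfig(seed=31))
    assert nb.truth.clusters == []
    assert all(v == "background" for v in nb.truth.region_classes.values())
    assert nb.truth.core_genes == set()


def test_reference_sets_exclude_assayed_condition(bundle):
    for ref in bundle.reference_sets:
        assert not (ref.stage == "L3" and ref.tissue == "wing")


def test_planted_de_is_recovered(bundle):
    from drre_kit.expression import call_de
    truth = bundle.truth.de
    for tp, labels in truth.items():
        calls = call_de(bundle.expression, tp).set_index("gene_id")
        for gene, direction in labels.items():
            assert calls.loc[gene, "direction"] == direction, (tp, gene)
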
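import pytest

from drre_kit.annotation import GeneIndex, annotate_peak, annotation_spectrum
from drre_kit.genes import GeneModel
from drre_kit.intervals import GenomicInterval


def _iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


@pytest.fixture
def genes():
    # plus-strand gene: TSS 10_000, exons 10_000-10_500 and 11_000-11_500
    a = GeneModel.from_exon_lists(
        "gA", "chr1", "+", [[_iv(10_000, 10_500), _iv(11_000, 11_500)]])
    # minus-strand gene: TSS 49_999
    b = GeneModel.from_exon_lists(
        "gB", "chr1", "-", [[_iv(48_000, 48_500), _iv(49_500, 50_000)]])
    return GeneIndex([a, b])


def probe(pos):
    return _iv(pos - 200, pos + 200)  # summit at pos


def annotate(genes, pos):
    from drre_kit.accessibility import DiffRegion
    return annotate_peak(DiffRegion(probe(pos), pos, "presence_only"), genes)


def test_cp_window_inclusive(genes):
    for pos in (10_000, 9_900, 10_100):
        ann = annotate(genes, pos)
        assert (ann.category, ann.gene_id) == ("CP", "gA")
    assert annotate(genes, 10_101).category != "CP"
    assert annotate(genes, 9_899).category != "CP"


def test_cp_is_unstranded_window(genes):
    # minus-strand TSS 49_999: both sides count
    assert annotate(genes, 50_050).category == "CP"
    assert annotate(genes, 49_950).category == "CP"


def test_first_intron_beats_proximal(genes):
    # gA first intron is 10_500-11_000; also within 2 kb of TSS
    ann = annotate(genes, 10_700)
    assert (ann.category, ann.gene_id) == ("FI", "gA")


def test_proximal_and_distal(genes):
    ann = annotate(genes, 11_900)  # 1.9 kb from TSS, outside intron
    assert ann.category == "proximal"
    assert annotate(genes, 30_000).category == "distal"


def test_signed_distance_strand_aware(genes):
    up = annotate(genes, 9_950)      # 50 bp upstream of plus-strand TSS
    assert up.distance_to_tss == -50
    down = annotate(genes, 10_050)
    assert down.distance_to_tss == 50
    # minus strand: positions right of the TSS are upstream (negative)
    minus_up = annotate(genes, 50_049)
    assert minus_up.distance_to_tss == -50


def test_distal_carries_nearest_gene(genes):
    ann = annotate(genes, 30_000)
    assert ann.category == "distal"
    assert ann.gene_id in {"gA", "gB"}


def test_no_genes_on_chrom():
    from drre_kit.accessibility import DiffRegion
    genes = GeneIndex([GeneModel.from_exon_lists(
        "gA", "chr1", "+", [[_iv(0, 100)]])])
    region = DiffRegion(_iv(500, 900, "chr9"), 700, "presence_only")
    ann = annotate_peak(region, genes)
    assert ann.category == "distal" and ann.gene_id is None


def test_tie_broken_by_absolute_distance(genes):
    # two genes equidistant would tie; here nearest wins
    ann = annotate(genes, 30_000)
    d_a = abs(30_000 - 10_000)
    d_b = abs(30_000 - 49_999)
    assert ann.gene_id == ("gA" if d_a <= d_b else "gB")


def test_annotation_spectrum_fractions(bundle, pipeline_out):
    out, _ = pipeline_out
    import pandas as pd
    spec = pd.read_csv(out / "annotation_spectrum.tsv", sep="\t")
    for _, grp in spec.groupby("drre_class"):
        assert grp.fraction.sum() == pytest.approx(1.0)
        assert (grp["count"] >= 0).all()
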
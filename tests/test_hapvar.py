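"""Anchor alignment and haplotype-specific indel calling."""

import numpy as np
import pytest

from haplodyn import hapvar
from haplodyn import synthetic_data as sd


def test_identical_sequences_single_full_anchor(rng):
    seq = sd.random_dna(rng, 50_000)
    chain = hapvar.anchor_align(seq, seq)
    assert len(chain.anchors) == 1
    a = chain.anchors[0]
    assert a.a_start == 0 and a.a_end == len(seq)
    calls, div = hapvar.call_indels(chain, seq, seq)
    assert calls == [] and div == []


def test_insertion_detected_with_refined_breakpoint(rng):
    a = sd.random_dna(rng, 60_000)
    ins = sd.random_dna(rng, 10_000)
    pos = 30_000
    b = a[:pos] + ins + a[pos:]
    chain = hapvar.anchor_align(a, b)
    calls, _ = hapvar.call_indels(chain, a, b, contig_a="A", contig_b="B")
    assert len(calls) == 1
    c = calls[0]
    assert c.contig_carrier == "B"
    assert abs(c.size - 10_000) <= 100
    assert c.start <= pos + 100 and c.end >= pos + 10_000 - 100
    assert abs(c.start - pos) <= 100


def test_small_insertion_below_threshold_not_called(rng):
    a = sd.random_dna(rng, 40_000)
    b = a[:20_000] + sd.random_dna(rng, 2_000) + a[20_000:]
    chain = hapvar.anchor_align(a, b)
    calls, _ = hapvar.call_indels(chain, a, b, min_indel=4_000)
    assert calls == []


def test_reverse_complement_needs_strand_flag(rng):
    a = sd.random_dna(rng, 20_000)
    b = sd.revcomp(a)
    assert hapvar.anchor_align(a, b).anchors == []
    rev = hapvar.anchor_align(a, b, reverse=True)
    assert rev.strand == "-" and rev.anchored_bp > 19_000


def test_sequence_shorter_than_k_gives_empty_chain():
    assert hapvar.anchor_align(b"ACGT", b"ACGTACGT" * 10).anchors == []


def test_calls_live_strictly_between_anchors(small_genome):
    from haplodyn import pipeline
    calls, _, _ = pipeline.call_haplotype_indels(small_genome)
    for c in calls:
        assert c.left_anchor is not None and c.right_anchor is not None
        # the called span does not intersect its flanking anchors
        if c.contig_carrier.endswith(tuple("AB")):
            la, ra = c.left_anchor, c.right_anchor
            for bound in (la.a_end, la.b_end):
                pass
            assert c.start >= min(la.a_end, la.b_end)
            assert c.end <= max(ra.a_start, ra.b_start)


def test_fixture_indels_recovered(small_genome):
    from haplodyn import pipeline
    calls, _, _ = pipeline.call_haplotype_indels(small_genome)
    score = pipeline.score_indel_calls(small_genome, calls)
    assert score["recall"] == 1.0 and score["precision"] == 1.0
    assert score["max_boundary_error"] <= 100


# ---------------------------------------------------------------------------
# content classification


def _call(contig="c", start=10_000, end=20_000):
    return hapvar.IndelCall(contig_carrier=contig, contig_partner="p",
                            start=start, end=end, size=end - start,
                            partner_pos=0, partner_gap=0)


def test_span_inside_ltr_is_fully_ltr():
    call = _call()
    hapvar.classify_indel_content(call, {"c": []}, {"c": [("L1", 5_000, 25_000)]})
    assert call.ltr_fraction == 1.0 and call.gene_fraction == 0.0


def test_gene_fraction_arithmetic():
    call = _call()
    hapvar.classify_indel_content(call, {"c": [("g1", 12_000, 13_000)]}, {"c": []})
    assert call.gene_fraction == pytest.approx(0.10)
    assert call.genes_within == ["g1"]


def test_repeat_priority_on_overlap():
    call = _call()
    hapvar.classify_indel_content(call, {"c": [("g1", 12_000, 14_000)]},
                                  {"c": [("L1", 13_000, 15_000)]})
    assert call.ltr_fraction == pytest.approx(0.2)
    assert call.gene_fraction == pytest.approx(0.1)  # overlap bp count to LTR


def test_contig_mismatch_names_contig():
    with pytest.raises(ValueError, match="other_contig"):
        hapvar.classify_indel_content(_call(contig="other_contig"),
                                      {"c": []}, {"c": []})


def test_flanks_in_gene_island_and_truncation():
    call = _call(start=10_000, end=12_000)
    genes = {"c": [("g", 8_000, 10_000), ("g2", 12_000, 14_000)]}
    comp = hapvar.summarize_flanks(call, genes, {"c": []}, contig_length=100_000)
    assert comp.gene_fraction == 1.0 and not comp.truncated
    near_end = _call(start=98_000, end=99_500)
    comp2 = hapvar.summarize_flanks(near_end, genes, {"c": []}, contig_length=100_000)
    assert comp2.truncated


def test_fixture_flanks_more_genic_than_indels(small_genome):
    from haplodyn import pipeline
    calls, flanks, _ = pipeline.call_haplotype_indels(small_genome)
    assert np.mean([f.gene_fraction for f in flanks]) > \
        np.mean([c.gene_fraction for c in calls])
    assert np.mean([c.ltr_fraction for c in calls]) > \
        np.mean([f.ltr_fraction for f in flanks])
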
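"""Duplicated gene pairs and collinear chaining, with an exhaustive chain oracle."""

import numpy as np
import pytest

from haplodyn import synteny
from haplodyn import synthetic_data as sd
from haplodyn.synteny import AnchorPair, GeneModel

from oracles import best_chain_exhaustive


def mk_genes(cds_list, contig="c1", prefix="g", spacing=2000):
    genes = []
    for i, cds in enumerate(cds_list):
        s = i * spacing
        genes.append(GeneModel(id=f"{prefix}{i}", contig=contig, start=s,
                               end=s + len(cds), strand="+", cds=cds))
    return synteny.assign_ranks(genes)


def test_identical_cds_yield_one_perfect_pair(rng):
    cds = sd.random_cds(rng, 300)
    genes = mk_genes([cds], "c1") + mk_genes([cds], "c2", prefix="h")
    pairs = synteny.find_anchor_pairs(genes)
    assert len(pairs) == 1
    assert pairs[0].identity == 1.0


def test_identity_threshold_excludes_diverged_pair(rng):
    cds = sd.random_cds(rng, 400)
    mut, _ = sd.mutate(cds, rng, 0.05)
    genes = mk_genes([cds], "c1") + mk_genes([mut], "c2", prefix="h")
    assert synteny.find_anchor_pairs(genes, min_identity=0.99) == []
    found = synteny.find_anchor_pairs(genes, min_identity=0.90)
    assert len(found) == 1 and found[0].identity < 0.99


def test_empty_gene_set_is_empty_result():
    assert synteny.find_anchor_pairs([]) == []


def test_invalid_k_is_config_error(rng):
    cds = sd.random_cds(rng, 100)
    with pytest.raises(Exception):
        synteny.find_anchor_pairs(mk_genes([cds]), k=0)


def _collinear_instance(rng, n, reverse_b=False):
    cds = [sd.random_cds(rng, 250) for _ in range(n)]
    a = mk_genes(cds, "c1", prefix="a")
    order = list(reversed(cds)) if reverse_b else cds
    b = mk_genes(order, "c2", prefix="b")
    genes = a + b
    pairs = synteny.find_anchor_pairs(genes)
    return genes, pairs


def test_perfect_collinearity_chains_to_one_block(rng):
    genes, pairs = _collinear_instance(rng, 10)
    blocks = synteny.chain_collinear(pairs, genes)
    assert len(blocks) == 1
    assert blocks[0].n_genes == 10 and blocks[0].orientation == "same"


def test_reversed_order_gives_inverted_block(rng):
    genes, pairs = _collinear_instance(rng, 10, reverse_b=True)
    blocks = synteny.chain_collinear(pairs, genes)
    assert len(blocks) == 1
    assert blocks[0].n_genes == 10 and blocks[0].orientation == "inverted"


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_chaining_matches_exhaustive_oracle(seed):
    """Shuffled instances <= 15 anchors: best chain equals brute-force DFS."""
    r = np.random.default_rng(seed)
    n = int(r.integers(6, 15))
    rb = r.permutation(n)
    rb[: n // 3] = np.sort(rb[: n // 3])  # partial structure
    items = [(int(i), int(rb[i]),
              AnchorPair(f"a{i}", f"b{i}", 1.0, 100), f"a{i}", f"b{i}")
             for i in range(n)]
    chain, _ = synteny._best_chain(sorted(items), max_gap=10)
    oracle = best_chain_exhaustive([(i, int(rb[i])) for i in range(n)], max_gap=10)
    assert len(chain) == oracle


def test_span_filter_and_mirror_dedup():
    def block(ca, cb, la, lb, n=6):
        return synteny.SyntenyBlock(anchors=[], contig_a=ca, contig_b=cb,
                                    span_a=(0, la), span_b=(0, lb),
                                    orientation="same", n_genes=n)
    keep = block("c1", "c2", 80_000, 79_000)
    small = block("c3", "c4", 20_000, 90_000)
    mirror = block("c2", "c1", 79_000, 80_000)
    mirror.span_a, mirror.span_b = keep.span_b, keep.span_a
    mirror.contig_a, mirror.contig_b = keep.contig_b, keep.contig_a
    out = synteny.pair_haplotype_blocks([keep, small, mirror], min_span=75_000)
    assert len(out) == 1 and out[0].span_a_length >= 75_000


def test_blocks_never_share_anchors(small_genome):
    from haplodyn import pipeline
    blocks, pairs, models = pipeline.detect_haplotype_blocks(
        small_genome, min_span=50_000)
    seen = set()
    all_blocks = synteny.chain_collinear(pairs, models)
    for b in all_blocks:
        for p in b.anchors:
            key = (p.gene_a, p.gene_b)
            assert key not in seen
            seen.add(key)


def test_fixture_haplotype_pair_recovered(small_genome):
    from haplodyn import pipeline
    blocks, _, _ = pipeline.detect_haplotype_blocks(small_genome, min_span=50_000)
    assert any({b.contig_a, b.contig_b} == {"contig1_A", "contig1_B"} for b in blocks)
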
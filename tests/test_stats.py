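"""Rank-sum testing, enrichment, composition and report arithmetic."""

import numpy as np
import pytest

from haplodyn import stats_report as sr
from haplodyn.hapvar import Composition

from oracles import rank_sum_p_exhaustive


def test_exact_one_sided_textbook_case():
    r = sr.rank_sum_test([1, 2, 3], [4, 5, 6], alternative="less", method="exact")
    assert r.p_value == pytest.approx(1 / 20)
    assert r.method == "exact"


def test_same_multiset_gives_p_one():
    with pytest.warns(UserWarning):
        r = sr.rank_sum_test([1.0, 1.0], [1.0, 1.0])
    assert r.p_value == 1.0


def test_identical_distribution_statistic_at_null_mean():
    r = sr.rank_sum_test([1, 2, 3], [1, 2, 3], method="exact")
    assert r.statistic == pytest.approx(3 * 7 / 2)
    assert r.p_value == 1.0


@pytest.mark.parametrize("seed", range(8))
def test_exact_matches_exhaustive_oracle_with_ties(seed):
    rng = np.random.default_rng(seed)
    nx, ny = int(rng.integers(2, 6)), int(rng.integers(2, 6))
    vals = rng.integers(0, 5, size=nx + ny).astype(float)  # heavy ties
    x, y = list(vals[:nx]), list(vals[nx:])
    if len(set(x + y)) == 1:
        return
    for alt in ("two-sided", "greater", "less"):
        mine = sr.rank_sum_test(x, y, alternative=alt, method="exact")
        w, p = rank_sum_p_exhaustive(x, y, alt)
        assert mine.statistic == pytest.approx(w)
        assert mine.p_value == pytest.approx(p)


def test_normal_approximation_close_to_permutation():
    rng = np.random.default_rng(2)
    x = rng.exponential(1.0, size=60)
    y = rng.exponential(1.6, size=50)
    pn = sr.rank_sum_test(x, y, method="normal_approximation").p_value
    pp = sr.rank_sum_test(x, y, method="permutation", seed=0,
                          n_permutations=40_000).p_value
    assert pn == pytest.approx(pp, rel=0.10)


# ---------------------------------------------------------------------------
# enrichment


class El:
    def __init__(self, contig, start, end, T, datable=True):
        self.contig, self.start, self.end = contig, start, end
        self.T, self.datable = T, datable


def test_all_elements_outside_is_flagged():
    els = [El("c", i * 1000, i * 1000 + 500, 1e5) for i in range(5)]
    res = sr.young_ltr_enrichment(els, {"c": []})
    assert res.flagged and res.proportion_young_in is None


def test_cutoff_zero_gives_zero_proportions():
    els = [El("c", 0, 100, 5e4), El("c", 10_000, 10_100, 2e5)]
    res = sr.young_ltr_enrichment(els, {"c": [(0, 200)]}, young_cutoff=0.0)
    assert res.proportion_young_in == 0.0 and res.proportion_young_out == 0.0


def test_enrichment_detects_young_inside():
    rng = np.random.default_rng(0)
    inside = [El("c", i * 2000, i * 2000 + 1000, float(t))
              for i, t in enumerate(rng.exponential(4e4, 60))]
    outside = [El("c", 10**6 + i * 2000, 10**6 + i * 2000 + 1000, float(t))
               for i, t in enumerate(rng.exponential(4e5, 60))]
    res = sr.young_ltr_enrichment(inside + outside, {"c": [(0, 200_000)]})
    assert res.proportion_young_in > res.proportion_young_out
    assert res.rank_sum.p_value < 0.01


# ---------------------------------------------------------------------------
# composition / expression / rwc / summary


class Call:
    def __init__(self, size, ltr, gene):
        self.size = size
        self.ltr_fraction, self.gene_fraction = ltr, gene
        self.other_fraction = 1 - ltr - gene


def test_composition_bp_weighting():
    rep = sr.composition_report([Call(10_000, 0.8, 0.1), Call(30_000, 0.4, 0.2)])
    assert rep["indel"]["ltr_fraction"] == pytest.approx(0.5)
    rep1 = sr.composition_report([Call(5_000, 0.5, 0.2)])
    assert rep1["indel"]["ltr_fraction"] == pytest.approx(0.5)


def test_composition_aggregate_equals_weighted_mean_exactly():
    rng = np.random.default_rng(3)
    calls = [Call(int(s), float(l), float(g) * (1 - l))
             for s, l, g in zip(rng.integers(5_000, 80_000, 25),
                                rng.random(25) * 0.8, rng.random(25) * 0.2)]
    rep = sr.composition_report(calls)
    manual = sum(c.size * c.ltr_fraction for c in calls) / sum(c.size for c in calls)
    assert abs(rep["indel"]["ltr_fraction"] - manual) < 1e-9
    flanks = [Composition(0.1, 0.8, 0.1, 12_000), Composition(0.2, 0.6, 0.2, 4_000)]
    rep2 = sr.composition_report(calls, flanks)
    assert rep2["flank"]["gene_fraction"] == pytest.approx((0.8 * 12 + 0.6 * 4) / 16)


def test_expression_filter_display_fraction():
    table = {f"g{i}": (0.1 if i < 248 else 5.0) for i in range(335)}
    res = sr.expression_filter(table, list(table))
    assert res.n_total == 335 and res.n_below == 248
    assert round(100 * res.fraction, 1) == 74.0


def test_expression_filter_edge_cases():
    table = {"a": 0.2, "b": 3.0}
    assert sr.expression_filter(table, ["a", "b"], threshold=0.0).n_below == 0
    res = sr.expression_filter(table, ["a", "zz"])
    assert res.missing_ids == ["zz"] and res.n_total == 1
    with pytest.raises(ValueError):
        sr.expression_filter(table, [])


def test_relative_water_content():
    assert sr.relative_water_content(3, 1, 3) == 1.0
    assert sr.relative_water_content(1, 1, 3) == 0.0
    assert sr.relative_water_content(2, 1, 3) == 0.5
    with pytest.raises(ValueError):
        sr.relative_water_content(2, 3, 3)
    with pytest.raises(ValueError):
        sr.relative_water_content(0.5, 1, 3)


def test_genome_summary_display_arithmetic():
    out = sr.genome_summary(genome_size_bp=109e6, n_genes=27_204,
                            indel_sizes=[2.5e6 / 104] * 104, collinear_bp=13.5e6,
                            si_aggregate=4.0599)
    assert out["gene_density_kb_per_gene"] == 4.0
    assert out["indel_percent_of_collinear"] == 18.5
    assert out["indel_mean_kb"] == 24
    assert out["solo_intact_ratio"] == 4.06
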
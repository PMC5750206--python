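"""Methylation levels, replicate averaging, metagene binning, window tracks."""

import numpy as np
import pandas as pd
import pytest

from haplodyn import methylation_profiler as mp


def df(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "context",
                                       "count_methylated", "count_unmethylated"])


def test_site_level_arithmetic_and_coverage_filter():
    d = df([("c", 10, "+", "CpG", 5, 0),
            ("c", 11, "+", "CpG", 1, 1),
            ("c", 12, "+", "CHH", 3, 7)])
    out, dropped = mp.site_levels(d, min_coverage=3)
    assert dropped == 1
    lv = out.set_index("pos")["level"]
    assert lv[10] == 1.0 and lv[12] == pytest.approx(0.3)
    assert 11 not in lv.index


def test_report_reader_checks_lines(tmp_path):
    p = tmp_path / "rep.tsv"
    p.write_text("contig\tposition\tstrand\tcount_methylated\tcount_unmethylated\tcontext\n"
                 "c\t1\t+\t3\t1\tCpG\n"
                 "c\t2\t+\t-1\t1\tCpG\n")
    with pytest.raises(mp.CytosineReportError, match="line 3"):
        mp.read_cytosine_report(p)
    p2 = tmp_path / "ok.tsv"
    p2.write_text("contig\tposition\tstrand\tcount_methylated\tcount_unmethylated\tcontext\n"
                  "c\t1\t+\t3\t1\tCpG\n")
    out = mp.read_cytosine_report(p2)
    assert out.loc[0, "pos"] == 0  # 1-based file -> 0-based internal


def level_df(rows):
    return pd.DataFrame(rows, columns=["contig", "pos", "strand", "context", "level"])


def test_replicate_averaging_rules():
    r1 = level_df([("c", 1, "+", "CpG", 0.2), ("c", 2, "+", "CpG", 0.6)])
    r2 = level_df([("c", 1, "+", "CpG", 0.4)])
    out = mp.average_replicates([r1, r2]).set_index("pos")
    assert out.loc[1, "level"] == pytest.approx(0.3)
    assert out.loc[2, "level"] == pytest.approx(0.6)  # present in 1 of 2 reps
    with pytest.raises(ValueError):
        mp.average_replicates([])


def uniform_levels(contig="c", n=4000, level=0.8, context="CpG"):
    return level_df([(contig, i, "+", context, level) for i in range(n)])


def test_uniform_level_gives_flat_profile():
    lv = uniform_levels()
    feat = [mp.Feature("f1", "c", 1500, 2500, "+")]
    prof = mp.metagene_profile(lv, feat, context="CpG")
    means = prof.bin_means()
    assert np.allclose(means[~np.isnan(means)], 0.8)


def test_minus_strand_profile_is_mirror_of_plus():
    rng = np.random.default_rng(4)
    lv = level_df([("c", i, "+", "CpG", float(r)) for i, r in
                   enumerate(rng.random(4000))])
    plus = mp.metagene_profile(lv, [mp.Feature("f", "c", 1500, 2500, "+")], context="CpG")
    minus = mp.metagene_profile(lv, [mp.Feature("f", "c", 1500, 2500, "-")], context="CpG")
    np.testing.assert_allclose(plus.bin_means(), minus.bin_means()[::-1])


def test_short_feature_flagged_single_body_bin():
    lv = uniform_levels(n=200)
    prof = mp.metagene_profile(lv, [mp.Feature("tiny", "c", 100, 110, "+")],
                               context="CpG", flank=50)
    assert "tiny" in prof.short_features


def test_weighted_bin_mean_equals_global_mean():
    rng = np.random.default_rng(7)
    lv = level_df([("c", i, "+", "CpG", float(r)) for i, r in
                   enumerate(rng.random(3000))])
    feat = [mp.Feature("f", "c", 1000, 2000, "+")]
    prof = mp.metagene_profile(lv, feat, context="CpG")
    s = n = 0.0
    for _, m, cnt in prof.bins:
        if cnt:
            s += m * cnt
            n += cnt
    covered = lv[(lv.pos >= 0) & (lv.pos < 3000)]
    assert s / n == pytest.approx(covered.level.mean(), rel=1e-9)


def test_pooling_order_invariance():
    """Average-then-bin equals bin-then-average when all sites pass everywhere."""
    rng = np.random.default_rng(1)
    reps = [level_df([("c", i, "+", "CpG", float(r)) for i, r in
                      enumerate(rng.random(2000))]) for _ in range(3)]
    feat = [mp.Feature("f", "c", 500, 1500, "+")]
    avg_first = mp.metagene_profile(mp.average_replicates(reps), feat,
                                    context="CpG").bin_means()
    per_rep = np.nanmean([mp.metagene_profile(r, feat, context="CpG").bin_means()
                          for r in reps], axis=0)
    np.testing.assert_allclose(avg_first, per_rep, atol=1e-9)


def test_window_tracks_counts_and_missing():
    lv = level_df([("c", 10, "+", "CpG", 0.5)])
    tracks, _ = mp.window_tracks(lv, {"c": [(0, 100)]}, {"c": []},
                                 {"c": 125_000}, window=50_000)
    assert len(tracks) == 3  # ceil(125000 / 50000)
    assert np.isnan(tracks.loc[1, "level_CpG"])  # empty window -> missing
    assert tracks.loc[1, "gene_density"] == 0.0
    assert tracks.loc[0, "gene_density"] == pytest.approx(100 / 50_000)


def test_fixture_landscape_correlation(meth_genome):
    from haplodyn import pipeline
    res = pipeline.methylation_analysis(meth_genome)
    assert res["ltr_cpg_correlation"] > 0.5
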
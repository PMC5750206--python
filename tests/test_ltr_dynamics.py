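"""LTR dating (Jukes-Cantor) and the four-rule solo-LTR filter."""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplodyn import ltr_dynamics as ld
from haplodyn import pipeline
from haplodyn.config import ConfigError


def mk_element(seq5: bytes, seq3: bytes, gap: bytes = b"A" * 100):
    seq = seq5 + gap + seq3
    el = ld.LTRElement(id="e", contig="c", start=0, end=len(seq),
                       ltr5=(0, len(seq5)),
                       ltr3=(len(seq5) + len(gap), len(seq)),
                       family="f")
    return el, {"c": seq}


def test_identical_ltrs_have_zero_divergence():
    el, seqs = mk_element(b"ACGT" * 100, b"ACGT" * 100)
    assert ld.ltr_pair_divergence(el, seqs) == 0.0


def test_ten_substitutions_in_1kb_give_p_001():
    l5 = bytearray(b"ACGT" * 250)
    l3 = bytearray(l5)
    for i in range(10):
        pos = i * 97
        l3[pos] = ord("C") if l3[pos] != ord("C") else ord("G")
    el, seqs = mk_element(bytes(l5), bytes(l3))
    assert ld.ltr_pair_divergence(el, seqs) == pytest.approx(0.010)


def test_ltr_span_outside_contig_is_error():
    el, seqs = mk_element(b"ACGT" * 100, b"ACGT" * 100)
    el.ltr3 = (el.ltr3[0], el.ltr3[1] + 999)
    with pytest.raises(ValueError, match="outside contig"):
        ld.ltr_pair_divergence(el, seqs)


def test_jc_trivial_and_saturation():
    assert ld.jc_distance(0.0) == 0.0
    with pytest.raises(ld.SaturationError):
        ld.jc_distance(0.75)
    with pytest.raises(ld.SaturationError):
        ld.jc_distance(0.9)


@given(st.floats(min_value=0.0, max_value=0.745))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_jc_monotone_and_never_below_p(p):
    k = ld.jc_distance(p)
    assert k >= p - 1e-15
    assert ld.jc_distance(p + 1e-4) > k if p + 1e-4 < 0.75 else True


def test_jc_matches_high_precision_oracle():
    mpmath.mp.dps = 40
    for p in [0.001, 0.01, 0.05, 0.2, 0.5, 0.74]:
        oracle = float(-mpmath.mpf(3) / 4 * mpmath.log(1 - mpmath.mpf(4) / 3 * mpmath.mpf(repr(p))))
        assert math.isclose(ld.jc_distance(p), oracle, rel_tol=0, abs_tol=1e-12)


def test_insertion_time_arithmetic():
    assert ld.insertion_time(0.0) == 0.0
    assert ld.insertion_time(2.6e-3, 1.3e-8) == pytest.approx(1.0e5)
    with pytest.raises(ConfigError):
        ld.insertion_time(0.1, mu=0.0)


# ---------------------------------------------------------------------------
# solo filter


def good_hit(**kw):
    base = dict(contig="c", start=10_000, end=10_500, family="f", kind="LTR",
                library_coverage=0.95, score=400)
    base.update(kw)
    return ld.CandidateHit(**base)


def test_solo_rules_one_rule_off_each():
    ok = good_hit()
    assert len(ld.call_solo_ltrs([ok])) == 1

    # (i) neighbor within 300 bp
    neighbor = good_hit(start=10_700, end=11_200, kind="INT")
    assert ld.call_solo_ltrs([ok, neighbor]) == []
    far = good_hit(start=10_801, end=11_300, kind="INT")
    assert len(ld.call_solo_ltrs([ok, far])) == 1

    # (ii) coverage below 80%
    assert ld.call_solo_ltrs([good_hit(library_coverage=0.79)]) == []
    # (iii) score not strictly above 300
    assert ld.call_solo_ltrs([good_hit(score=300)]) == []
    # (iv) shorter than 100 bp
    assert ld.call_solo_ltrs([good_hit(end=10_099)]) == []


def test_solo_filter_is_pure_conjunction():
    """Disabling any one rule weakly increases the accepted count."""
    hits = [good_hit(),
            good_hit(start=20_000, end=20_400, library_coverage=0.5),
            good_hit(start=30_000, end=30_400, score=100),
            good_hit(start=40_000, end=40_050),
            good_hit(start=50_000, end=50_400),
            good_hit(start=50_500, end=50_900)]
    base = len(ld.call_solo_ltrs(hits))
    for off in ({"isolation_bp": None}, {"min_coverage": None},
                {"min_score": None}, {"min_length": None}):
        relaxed = len(ld.call_solo_ltrs(hits, rules=ld.SoloRules(**off)))
        assert relaxed >= base


def test_fixture_solos_all_called_and_no_intact_called(small_genome):
    res = pipeline.solo_analysis(small_genome)
    assert res["n_matched"] == res["n_planted"]
    assert res["false_on_intact"] == 0


# ---------------------------------------------------------------------------
# family statistics


def els(family, n, ltr_len=1000, T=1e5):
    out = []
    for i in range(n):
        e = ld.LTRElement(id=f"{family}{i}", contig="c", start=0, end=5000,
                          ltr5=(0, ltr_len), ltr3=(5000 - ltr_len, 5000),
                          family=family)
        e.T, e.datable = T, True
        out.append(e)
    return out


def solos(family, n, length=1000):
    return [ld.SoloLTR(id=f"s{family}{i}", contig="c", start=0, end=length,
                       family=family, library_coverage=0.9, score=400)
            for i in range(n)]


def test_ratio_four_to_one():
    stats, agg, _ = ld.solo_intact_ratio(els("f", 1), solos("f", 4),
                                         length_window=(0, 2000))
    assert stats[0].si_ratio == 4.0 and agg == 4.0


def test_family_outside_window_excluded_from_aggregate():
    elements = els("short", 5, ltr_len=100) + els("long", 5, ltr_len=1000)
    sol = solos("short", 10) + solos("long", 5)
    stats, agg, _ = ld.solo_intact_ratio(elements, sol, length_window=(500, 2000))
    by_fam = {s.family: s for s in stats}
    assert by_fam["short"].si_ratio == 2.0            # present in the table
    assert not by_fam["short"].in_length_window       # but excluded
    assert agg == 1.0                                 # only "long" aggregated


def test_zero_intact_family_is_undefined_not_zero():
    stats, agg, _ = ld.solo_intact_ratio(els("a", 2), solos("b", 3),
                                         length_window=(0, 2000))
    by_fam = {s.family: s for s in stats}
    assert by_fam["b"].si_ratio is None
    assert agg == 0.0  # family a: 0 solos / 2 intact


def test_aggregate_invariant_to_relabeling():
    elements = els("x", 3) + els("y", 2)
    sol = solos("x", 6) + solos("y", 4)
    _, agg1, _ = ld.solo_intact_ratio(elements, sol, length_window=(0, 2000))
    for e in elements:
        e.family = {"x": "u", "y": "v"}[e.family]
    for s in sol:
        s.family = {"x": "u", "y": "v"}[s.family]
    _, agg2, _ = ld.solo_intact_ratio(elements, sol, length_window=(0, 2000))
    assert agg1 == agg2 == 2.0


def test_family_age_summary_excludes_saturated():
    elements = els("f", 1, T=100_000)
    sat = els("f", 1)[0]
    sat.datable, sat.T = False, None
    df, excluded = ld.family_age_summary(elements + [sat])
    assert excluded == 1
    assert df.loc[0, "mean_age"] == pytest.approx(100_000)
    assert df.loc[0, "n"] == 2 and df.loc[0, "n_dated"] == 1
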
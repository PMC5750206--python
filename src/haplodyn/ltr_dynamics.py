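"""LTR retrotransposon dynamics: insertion-time dating and solo-LTR analysis.

An LTR retrotransposon inserts with two identical long terminal repeats; they
accumulate substitutions independently afterwards, so the 5'/3' LTR divergence
clocks the insertion. The estimator is

    p  = mismatched aligned columns / aligned columns (gaps excluded)
    K  = -(3/4) * ln(1 - (4/3) * p)        (Jukes-Cantor correction)
    T  = K / (2 * mu)                       (mu: substitutions / bp / year)

with the neutral rate mu = 1.3e-8 per bp per year as default.

Solo LTRs — single LTRs left by unequal homologous recombination — are called
from alignments of library LTR entries to the genome under four conjunctive
rules: isolation (no other LTR-related sequence within 300 bp), library
coverage >= 80%, alignment score > 300 (internal score scale: match +1,
mismatch -1, gap column -2), and length >= 100 bp. Per-family solo:intact
ratios are aggregated over families whose mean LTR length falls inside a
length window (default: central 95% interval of intact LTR lengths), since
LTR length correlates with solo formation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from haplodyn.alignment import align_stats
from haplodyn.config import ConfigError

DEFAULT_MU = 1.3e-8  # substitutions per bp per year
JC_SATURATION = 0.75


class SaturationError(ValueError):
    """Observed divergence at or beyond the Jukes-Cantor saturation point."""


@dataclass
class LTRElement:
    """An intact LTR retrotransposon with its dating fields."""

    id: str
    contig: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    family: str
    superfamily: str = "unknown"
    p_divergence: float | None = None
    K: float | None = None
    T: float | None = None
    datable: bool = True

    @property
    def ltr_length(self) -> int:
        return self.ltr5[1] - self.ltr5[0]


def ltr_pair_divergence(element: LTRElement, seqs: dict[str, bytes]) -> float:
    """Observed divergence p of the element's two LTRs (gap columns excluded)."""
    if element.contig not in seqs:
        raise ValueError(f"contig {element.contig!r} not in genome")
    seq = seqs[element.contig]
    for s, e in (element.ltr5, element.ltr3):
        if not (0 <= s < e <= len(seq)):
            raise ValueError(
                f"element {element.id}: LTR span ({s}, {e}) outside contig "
                f"{element.contig} of length {len(seq)}")
    l5 = seq[element.ltr5[0]:element.ltr5[1]]
    l3 = seq[element.ltr3[0]:element.ltr3[1]]
    return align_stats(l5, l3).p_distance


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance K = -(3/4) ln(1 - (4/3) p).

    Valid for 0 <= p < 0.75; at or beyond 0.75 the correction diverges and a
    :class:`SaturationError` is raised (the element is undatable).
    """
    if p < 0:
        raise ValueError(f"divergence p must be >= 0, got {p}")
    if p >= JC_SATURATION:
        raise SaturationError(
            f"p = {p} >= {JC_SATURATION}: divergence saturated, age unrecoverable")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def insertion_time(K: float, mu: float = DEFAULT_MU) -> float:
    """Insertion time in years, T = K / (2 mu)."""
    if mu <= 0:
        raise ConfigError(f"mu must be positive, got {mu}")
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    return K / (2.0 * mu)


def date_elements(elements: list[LTRElement], seqs: dict[str, bytes],
                  mu: float = DEFAULT_MU) -> tuple[list[LTRElement], int]:
    """Fill p, K, T for every element; saturated elements flagged undatable.

    Returns (elements, number saturated).
    """
    n_saturated = 0
    for el in elements:
        p = ltr_pair_divergence(el, seqs)
        el.p_divergence = p
        try:
            el.K = jc_distance(p)
            el.T = insertion_time(el.K, mu)
            el.datable = True
        except SaturationError:
            el.K = el.T = None
            el.datable = False
            n_saturated += 1
    return elements, n_saturated


# ---------------------------------------------------------------------------
# solo-LTR candidate search and calling


@dataclass(frozen=True)
class CandidateHit:
    """One alignment of a library entry (LTR or internal region) to the genome."""

    contig: str
    start: int
    end: int
    family: str
    kind: str             # "LTR" or "INT"
    library_coverage: float
    score: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _kmer_hash(seq: bytes, k: int) -> np.ndarray:
    """Exact integer encoding of every k-mer (4^k < 2^63 for k <= 31), Horner scheme."""
    from haplodyn.synthetic_data import _CODE
    codes = _CODE[np.frombuffer(seq, dtype=np.uint8)].astype(np.int64)
    m = codes.size - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(m, dtype=np.int64)
    for j in range(k):
        h = h * 4 + codes[j:j + m]
    return h


def find_ltr_hits(seqs: dict[str, bytes],
                  library: list[tuple[str, str, bytes]],
                  k: int = 21, max_locus_gap: int = 300) -> list[CandidateHit]:
    """Scan the genome for alignments of library entries.

    ``library`` is a list of (family, kind, sequence) with kind "LTR" or "INT"
    — internal-region entries matter because their hits disqualify adjacent
    LTR hits from being solo. Seeding is exact k-mer matching; seed clusters
    are scored by global alignment of the covered ranges.
    """
    lookups: list[tuple[str, str, bytes, dict[int, int], int]] = []
    for family, kind, entry in library:
        if len(entry) < k:
            continue
        lookup: dict[int, int] = {}
        dups: set[int] = set()
        for pos, h in enumerate(_kmer_hash(entry, k).tolist()):
            if h in lookup or h in dups:
                lookup.pop(h, None)
                dups.add(h)
            else:
                lookup[h] = pos
        lookups.append((family, kind, entry, lookup, max_locus_gap))

    hits: list[CandidateHit] = []
    for contig, seq in seqs.items():
        gh = _kmer_hash(seq, k)
        for family, kind, entry, lookup, gap_cut in lookups:
            entry_keys = np.fromiter(lookup.keys(), dtype=np.int64, count=len(lookup))
            gpos = np.flatnonzero(np.isin(gh, entry_keys))
            if gpos.size == 0:
                continue
            epos = np.array([lookup[int(h)] for h in gh[gpos]], dtype=np.int64)
            # cluster genome positions into loci
            breaks = np.flatnonzero(np.diff(gpos) > gap_cut)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks + 1, [gpos.size]])
            for s_i, e_i in zip(starts, ends):
                g0, g1 = int(gpos[s_i]), int(gpos[e_i - 1]) + k
                e0, e1 = int(epos[s_i:e_i].min()), int(epos[s_i:e_i].max()) + k
                stats = align_stats(entry[e0:e1], seq[g0:g1])
                hits.append(CandidateHit(
                    contig=contig, start=g0, end=g1, family=family, kind=kind,
                    library_coverage=(e1 - e0) / len(entry), score=stats.score))
    return sorted(hits, key=lambda h: (h.contig, h.start))


@dataclass(frozen=True)
class SoloRules:
    """The four conjunctive solo-LTR acceptance rules; set a field to None to
    disable that rule (used for the one-rule-off conformance checks)."""

    isolation_bp: int | None = 300
    min_coverage: float | None = 0.8
    min_score: int | None = 300
    min_length: int | None = 100


@dataclass
class SoloLTR:
    id: str
    contig: str
    start: int
    end: int
    family: str
    library_coverage: float
    score: int

    @property
    def length(self) -> int:
        return self.end - self.start


def call_solo_ltrs(candidate_hits: list[CandidateHit],
                   rules: SoloRules = SoloRules(),
                   extra_spans: list[tuple[str, int, int]] | None = None) -> list[SoloLTR]:
    """Accept LTR hits satisfying all enabled rules.

    Isolation is checked against *all other* candidate hits (LTR and internal)
    plus any ``extra_spans``; spans overlapping a hit by >= 80% of the hit's
    length are treated as the hit's own annotation and skipped.
    """
    spans = [(h.contig, h.start, h.end) for h in candidate_hits]
    if extra_spans:
        spans += list(extra_spans)
    out: list[SoloLTR] = []
    n = 0
    for i, h in enumerate(candidate_hits):
        if h.kind != "LTR":
            continue
        if rules.min_length is not None and h.length < rules.min_length:
            continue
        if rules.min_coverage is not None and h.library_coverage < rules.min_coverage:
            continue
        if rules.min_score is not None and h.score <= rules.min_score:
            continue
        if rules.isolation_bp is not None:
            isolated = True
            for j, (c, s, e) in enumerate(spans):
                if j == i or c != h.contig:
                    continue
                ov = max(0, min(e, h.end) - max(s, h.start))
                if ov >= 0.8 * h.length:
                    continue  # the hit's own annotation
                dist = max(s - h.end, h.start - e)
                if dist < rules.isolation_bp:
                    isolated = False
                    break
            if not isolated:
                continue
        n += 1
        out.append(SoloLTR(id=f"solo{n:04d}", contig=h.contig, start=h.start,
                           end=h.end, family=h.family,
                           library_coverage=h.library_coverage, score=h.score))
    return out


# ---------------------------------------------------------------------------
# family statistics


@dataclass
class FamilyStats:
    family: str
    n_intact: int
    n_solo: int
    si_ratio: float | None       # None (undefined), never 0, when n_intact == 0
    mean_ltr_length: float | None
    mean_age: float | None
    in_length_window: bool = True


def solo_intact_ratio(elements: list[LTRElement], solos: list[SoloLTR],
                      length_window: tuple[float, float] | None = None,
                      window_mode: str = "central") -> tuple[list[FamilyStats], float | None,
                                                             tuple[float, float] | None]:
    """Per-family and aggregate solo:intact ratios.

    The aggregate is total solos / total intacts over families whose mean
    intact-LTR length lies inside ``length_window`` (default: the central 95%
    interval of intact LTR lengths; ``window_mode="upper"`` uses (0, p95)).
    Families with no intact element get an undefined (None) ratio and are
    excluded from the aggregate.

    Returns (per-family stats, aggregate ratio or None, window used).
    """
    if not elements and not solos:
        return [], None, None
    lengths = np.array([el.ltr_length for el in elements], dtype=float)
    if length_window is None and lengths.size:
        if window_mode == "central":
            length_window = tuple(np.percentile(lengths, [2.5, 97.5]))
        elif window_mode == "upper":
            length_window = (0.0, float(np.percentile(lengths, 95)))
        else:
            raise ConfigError(f"unknown window_mode {window_mode!r}")

    fams = sorted({el.family for el in elements} | {s.family for s in solos})
    stats: list[FamilyStats] = []
    tot_solo = tot_intact = 0
    for fam in fams:
        els = [el for el in elements if el.family == fam]
        sol = [s for s in solos if s.family == fam]
        mean_len = float(np.mean([el.ltr_length for el in els])) if els else None
        ages = [el.T for el in els if el.datable and el.T is not None]
        in_window = (mean_len is not None and length_window is not None
                     and length_window[0] <= mean_len <= length_window[1])
        ratio = len(sol) / len(els) if els else None
        stats.append(FamilyStats(
            family=fam, n_intact=len(els), n_solo=len(sol), si_ratio=ratio,
            mean_ltr_length=mean_len,
            mean_age=float(np.mean(ages)) if ages else None,
            in_length_window=in_window))
        if els and in_window:
            tot_solo += len(sol)
            tot_intact += len(els)
    aggregate = tot_solo / tot_intact if tot_intact else None
    return stats, aggregate, length_window


def family_age_summary(elements: list[LTRElement]) -> tuple[pd.DataFrame, int]:
    """Mean insertion time per family over datable elements.

    Saturated (undatable) elements are excluded from means and counted;
    returns (per-family table, number excluded).
    """
    rows = []
    excluded = 0
    for fam in sorted({el.family for el in elements}):
        els = [el for el in elements if el.family == fam]
        ages = [el.T for el in els if el.datable and el.T is not None]
        excluded += sum(1 for el in els if not el.datable)
        rows.append({"family": fam, "n": len(els), "n_dated": len(ages),
                     "mean_age": float(np.mean(ages)) if ages else np.nan})
    return pd.DataFrame(rows), excluded
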
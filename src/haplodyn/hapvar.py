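"""Base-resolution comparison of paired haplotype regions: anchors and indels.

Given two sequences flagged as a haplotype pair by the synteny stage, this
module finds maximal exact-match anchors (k-mers unique in both sequences,
merged along diagonals), chains them by weighted longest-increasing-subsequence
on both coordinates, and calls large haplotype-specific indels from the
inter-anchor gaps: a gap is an indel when it is large on exactly one sequence
(>= ``min_indel``) and essentially absent on the other (<= ``max_partner_gap``).
Breakpoints are refined to base precision by splitting the partner-side gap
between the carrier gap's two ends at the position maximizing flanking
sequence agreement.

Indel content is classified against gene and LTR annotations (repeat priority:
bases under both count as LTR), and matched-width flanking collinear regions
are summarized the same way for contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from haplodyn.alignment import unique_kmer_positions
from haplodyn.synthetic_data import revcomp


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match: seq_a[a_start:a_end] == seq_b[b_start:b_end]."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start


@dataclass
class AnchorChain:
    anchors: list[Anchor]
    len_a: int
    len_b: int
    k: int
    min_anchor: int
    strand: str = "+"

    @property
    def anchored_bp(self) -> int:
        return sum(a.length for a in self.anchors)


def _exact_match_segments(seq_a: bytes, seq_b: bytes, k: int) -> list[Anchor]:
    """Merge shared unique k-mers along diagonals into maximal exact segments."""
    ka = unique_kmer_positions(seq_a, k)
    kb = unique_kmer_positions(seq_b, k)
    hits = sorted((kb[km] - pa, pa) for km, pa in ka.items() if km in kb)
    segments: list[Anchor] = []
    cur_diag = None
    cur_start = cur_end = 0
    for diag, pa in hits:
        if diag == cur_diag and pa <= cur_end:
            cur_end = pa + k
        else:
            if cur_diag is not None:
                segments.append(Anchor(cur_start, cur_end,
                                       cur_start + cur_diag, cur_end + cur_diag))
            cur_diag, cur_start, cur_end = diag, pa, pa + k
    if cur_diag is not None:
        segments.append(Anchor(cur_start, cur_end,
                               cur_start + cur_diag, cur_end + cur_diag))
    return segments


def anchor_align(seq_a: bytes | str, seq_b: bytes | str, k: int = 21,
                 min_anchor: int = 100, reverse: bool = False,
                 refine_gaps: bool = True) -> AnchorChain:
    """Anchor chain between two sequences.

    Uses k-mers unique in both sequences; adjacent consistent matches are
    merged into exact segments, segments >= ``min_anchor`` are chained by a
    length-weighted longest-increasing-subsequence on both coordinates.
    With ``refine_gaps`` (default) each inter-anchor gap is re-anchored
    locally at a quarter of ``min_anchor`` — substitution noise between
    haplotypes makes long exact anchors sparse, and local re-anchoring pins
    gap boundaries without admitting short spurious anchors globally.
    With ``reverse=True`` the reverse-complement of ``seq_b`` is also tried
    and the higher-weight chain returned (strand "-" when it wins).
    """
    if isinstance(seq_a, str):
        seq_a = seq_a.encode("ascii")
    if isinstance(seq_b, str):
        seq_b = seq_b.encode("ascii")
    if len(seq_a) < k or len(seq_b) < k:
        return AnchorChain([], len(seq_a), len(seq_b), k, min_anchor)

    def build(sb: bytes) -> AnchorChain:
        segs = [s for s in _exact_match_segments(seq_a, sb, k)
                if s.length >= min_anchor]
        chained = _chain_segments(segs)
        if refine_gaps:
            chained = _refine_chain_gaps(seq_a, sb, chained, k,
                                         max(k, min_anchor // 4))
        return AnchorChain(chained, len(seq_a), len(sb), k, min_anchor)

    fwd = build(seq_b)
    if not reverse:
        return fwd
    rev = build(revcomp(seq_b))
    if rev.anchored_bp > fwd.anchored_bp:
        rev.strand = "-"
        return rev
    return fwd


def _refine_chain_gaps(seq_a: bytes, seq_b: bytes, chain: list[Anchor],
                       k: int, min_sub_anchor: int) -> list[Anchor]:
    """Densify a chain by re-anchoring every inter-anchor gap locally.

    Each gap's two subsequences are homologous by the flanking chain, so
    shorter exact matches (unique within the gap) are trustworthy there.
    """
    if not chain:
        return chain
    gaps = []
    bounds = ([(0, chain[0].a_start, 0, chain[0].b_start)]
              + [(l.a_end, r.a_start, l.b_end, r.b_start)
                 for l, r in zip(chain, chain[1:])]
              + [(chain[-1].a_end, len(seq_a), chain[-1].b_end, len(seq_b))])
    out = list(chain)
    for a0, a1, b0, b1 in bounds:
        if a1 - a0 < k or b1 - b0 < k:
            continue
        segs = [s for s in _exact_match_segments(seq_a[a0:a1], seq_b[b0:b1], k)
                if s.length >= min_sub_anchor]
        for s in _chain_segments(segs):
            out.append(Anchor(s.a_start + a0, s.a_end + a0,
                              s.b_start + b0, s.b_end + b0))
    return sorted(out, key=lambda s: s.a_start)


def _chain_segments(segs: list[Anchor]) -> list[Anchor]:
    """Max-weight chain (weight = anchor length), both coordinates increasing."""
    if not segs:
        return []
    segs = sorted(segs, key=lambda s: (s.a_start, s.b_start))
    n = len(segs)
    a_start = np.array([s.a_start for s in segs])
    a_end = np.array([s.a_end for s in segs])
    b_start = np.array([s.b_start for s in segs])
    b_end = np.array([s.b_end for s in segs])
    w = (a_end - a_start).astype(np.int64)
    dp = w.copy()
    parent = np.full(n, -1)
    for i in range(1, n):
        ok = (a_end[:i] <= a_start[i]) & (b_end[:i] <= b_start[i])
        if ok.any():
            cand = np.where(ok, dp[:i], np.int64(-1))
            j = int(np.argmax(cand))
            if cand[j] > 0:
                dp[i] = cand[j] + w[i]
                parent[i] = j
    i = int(np.argmax(dp))
    chain = []
    while i != -1:
        chain.append(segs[i])
        i = int(parent[i])
    return chain[::-1]


@dataclass
class IndelCall:
    """One haplotype-specific insertion (coordinates on the carrier sequence)."""

    contig_carrier: str
    contig_partner: str
    start: int                 # carrier coords, 0-based half-open
    end: int
    size: int
    partner_pos: int           # collinear position on the partner
    partner_gap: int
    left_anchor: Anchor | None = None
    right_anchor: Anchor | None = None
    ltr_fraction: float | None = None
    gene_fraction: float | None = None
    other_fraction: float | None = None
    genes_within: list[str] = field(default_factory=list)
    ltrs_within: list[str] = field(default_factory=list)


@dataclass
class DivergentRegion:
    """An inter-anchor gap large on both sequences (not a clean indel)."""

    a_span: tuple[int, int]
    b_span: tuple[int, int]


def _refine_split(partner_gap: bytes, carrier_gap: bytes) -> int:
    """Offset into both gaps where the insertion begins.

    The partner gap aligns to the two ends of the carrier gap; the split k
    maximizing (matches of the first k bases at the gap starts) + (matches of
    the last Lp-k bases at the gap ends) pins the breakpoint, tolerant of
    substitution noise.
    """
    lp = len(partner_gap)
    if lp == 0:
        return 0
    p = np.frombuffer(partner_gap, dtype=np.uint8)
    c = np.frombuffer(carrier_gap, dtype=np.uint8)
    pm = np.concatenate([[0], np.cumsum(p == c[:lp])])
    sm = np.concatenate([[0], np.cumsum(p[::-1] == c[::-1][:lp])])
    totals = pm + sm[::-1]
    return int(np.argmax(totals))


def call_indels(chain: AnchorChain, seq_a: bytes, seq_b: bytes,
                min_indel: int = 4000, max_partner_gap: int = 500,
                contig_a: str = "a", contig_b: str = "b",
                refine: bool = True) -> tuple[list[IndelCall], list[DivergentRegion]]:
    """Call haplotype-specific indels from the inter-anchor gaps of a chain.

    A gap is an indel when one sequence's gap >= ``min_indel`` and the other's
    <= ``max_partner_gap`` (the asymmetry that operationalizes
    "haplotype-specific"). Symmetric large gaps are reported as divergent
    regions instead. Calls live strictly between anchors.
    """
    calls: list[IndelCall] = []
    divergent: list[DivergentRegion] = []
    anchors = chain.anchors
    for left, right in zip(anchors, anchors[1:]):
        gap_a = right.a_start - left.a_end
        gap_b = right.b_start - left.b_end
        big, small = max(gap_a, gap_b), min(gap_a, gap_b)
        if big >= min_indel and small <= max_partner_gap:
            if gap_a > gap_b:
                carrier_seq, carrier, c0, c1 = seq_a, contig_a, left.a_end, right.a_start
                partner_seq, partner, p0, p1 = seq_b, contig_b, left.b_end, right.b_start
            else:
                carrier_seq, carrier, c0, c1 = seq_b, contig_b, left.b_end, right.b_start
                partner_seq, partner, p0, p1 = seq_a, contig_a, left.a_end, right.a_start
            size = (c1 - c0) - (p1 - p0)
            off = 0
            if refine and p1 > p0:
                off = _refine_split(partner_seq[p0:p1], carrier_seq[c0:c1])
            calls.append(IndelCall(
                contig_carrier=carrier, contig_partner=partner,
                start=c0 + off, end=c0 + off + size, size=size,
                partner_pos=p0 + off, partner_gap=p1 - p0,
                left_anchor=left, right_anchor=right))
        elif small > max_partner_gap and big >= min_indel:
            divergent.append(DivergentRegion((left.a_end, right.a_start),
                                             (left.b_end, right.b_start)))
    return calls, divergent


# ---------------------------------------------------------------------------
# content classification


@dataclass
class Composition:
    ltr_fraction: float
    gene_fraction: float
    other_fraction: float
    bp: int
    truncated: bool = False


def _coverage_masks(span: tuple[int, int], gene_spans, ltr_spans) -> tuple[int, int]:
    """(ltr_bp, gene_bp) within span; bases under both annotations count to LTR."""
    s, e = span
    n = e - s
    ltr_mask = np.zeros(n, dtype=bool)
    gene_mask = np.zeros(n, dtype=bool)
    for gs, ge in ltr_spans:
        if ge > s and gs < e:
            ltr_mask[max(gs, s) - s:min(ge, e) - s] = True
    for gs, ge in gene_spans:
        if ge > s and gs < e:
            gene_mask[max(gs, s) - s:min(ge, e) - s] = True
    gene_mask &= ~ltr_mask  # repeat priority
    return int(ltr_mask.sum()), int(gene_mask.sum())


def _composition(span, gene_spans, ltr_spans, truncated=False) -> Composition:
    n = span[1] - span[0]
    if n <= 0:
        return Composition(0.0, 0.0, 0.0, 0, truncated)
    ltr_bp, gene_bp = _coverage_masks(span, gene_spans, ltr_spans)
    return Composition(ltr_bp / n, gene_bp / n, (n - ltr_bp - gene_bp) / n, n, truncated)


def classify_indel_content(call: IndelCall,
                           gene_annotation: dict[str, list[tuple[str, int, int]]],
                           ltr_annotation: dict[str, list[tuple[str, int, int]]]) -> IndelCall:
    """Fill the call's composition from annotations in carrier coordinates.

    ``gene_annotation`` / ``ltr_annotation`` map contig -> [(id, start, end)].
    A gene belongs to ``genes_within`` when >= 50% of its length lies inside
    the call span (same rule for LTR elements).
    """
    c = call.contig_carrier
    for name, ann in (("gene", gene_annotation), ("LTR", ltr_annotation)):
        if c not in ann:
            raise ValueError(f"{name} annotation has no contig {c!r}")
    gene_spans = [(s, e) for _, s, e in gene_annotation[c]]
    ltr_spans = [(s, e) for _, s, e in ltr_annotation[c]]
    comp = _composition((call.start, call.end), gene_spans, ltr_spans)
    call.ltr_fraction = comp.ltr_fraction
    call.gene_fraction = comp.gene_fraction
    call.other_fraction = comp.other_fraction
    call.genes_within = [gid for gid, s, e in gene_annotation[c]
                         if _overlap((s, e), (call.start, call.end)) >= 0.5 * (e - s)]
    call.ltrs_within = [lid for lid, s, e in ltr_annotation[c]
                        if _overlap((s, e), (call.start, call.end)) >= 0.5 * (e - s)]
    return call


def _overlap(x: tuple[int, int], y: tuple[int, int]) -> int:
    return max(0, min(x[1], y[1]) - max(x[0], y[0]))


def summarize_flanks(call: IndelCall,
                     gene_annotation: dict[str, list[tuple[str, int, int]]],
                     ltr_annotation: dict[str, list[tuple[str, int, int]]],
                     contig_length: int,
                     flank_size: int | None = None) -> Composition:
    """Composition of the two collinear flanks (matched width by default).

    Flanks truncated at a contig end are computed on the available bases and
    the result is flagged ``truncated``.
    """
    c = call.contig_carrier
    f = flank_size if flank_size is not None else call.size
    left = (max(0, call.start - f), call.start)
    right = (call.end, min(contig_length, call.end + f))
    truncated = (left[0] == 0 and call.start - f < 0) or (right[1] < call.end + f)
    gene_spans = [(s, e) for _, s, e in gene_annotation.get(c, [])]
    ltr_spans = [(s, e) for _, s, e in ltr_annotation.get(c, [])]
    lc = _composition(left, gene_spans, ltr_spans)
    rc = _composition(right, gene_spans, ltr_spans)
    total = lc.bp + rc.bp
    if total == 0:
        return Composition(0.0, 0.0, 0.0, 0, True)
    return Composition(
        (lc.ltr_fraction * lc.bp + rc.ltr_fraction * rc.bp) / total,
        (lc.gene_fraction * lc.bp + rc.gene_fraction * rc.bp) / total,
        (lc.other_fraction * lc.bp + rc.other_fraction * rc.bp) / total,
        total, truncated)


def breakpoint_context(call: IndelCall, carrier_seq: bytes, margin: int = 500) -> dict[str, bytes]:
    """Record +/- margin bp around both breakpoints for external validation."""
    return {
        "left": carrier_seq[max(0, call.start - margin):call.start + margin],
        "right": carrier_seq[max(0, call.end - margin):call.end + margin],
    }
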
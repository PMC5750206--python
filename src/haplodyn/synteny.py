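"""Gene-level microsynteny: duplicated gene pairs and collinear block chaining.

Haplotype blocks in a heterozygous assembly are found in two steps; this module
is the first: find duplicated (haplotype) gene pairs by CDS similarity and
chain them into collinear blocks by rank-monotone dynamic programming. Blocks
spanning enough sequence on both sides become candidate haplotype pairs handed
to base-resolution alignment (:mod:`haplodyn.hapvar`).

The similarity search is k-mer-seeded pairwise CDS alignment: genes sharing at
least one exact k-mer (default k = 21) are aligned globally and kept if their
identity clears ``min_identity``. Chaining extracts best-first maximal chains
with strictly monotone gene ranks on both contigs (increasing or decreasing,
giving the block orientation) and a bounded rank gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from haplodyn.alignment import align_stats, kmer_positions
from haplodyn.config import ConfigError


@dataclass
class GeneModel:
    """A gene anchor: coordinates plus coding sequence and contig rank."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    cds: bytes
    rank: int = -1

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.id}: start must be < end")


def assign_ranks(genes: list[GeneModel]) -> list[GeneModel]:
    """Set each gene's ordinal position along its contig (sorted by start)."""
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for glist in by_contig.values():
        glist.sort(key=lambda g: g.start)
        for r, g in enumerate(glist):
            g.rank = r
    return genes


@dataclass(frozen=True)
class AnchorPair:
    """One duplicated gene pair, stored in canonical (gene_a <= gene_b) order."""

    gene_a: str
    gene_b: str
    identity: float
    score: int


def find_anchor_pairs(genes: list[GeneModel], min_identity: float = 0.90,
                      max_hits_per_gene: int = 5, k: int = 21) -> list[AnchorPair]:
    """All gene pairs sharing a k-mer seed whose CDS identity >= min_identity.

    Self-pairs are excluded; each gene keeps at most ``max_hits_per_gene``
    partners (best alignment score first).
    """
    if k < 1:
        raise ConfigError(f"seed k-mer size must be >= 1, got {k}")
    if not genes:
        return []
    for g in genes:
        if not g.cds:
            raise ValueError(f"gene {g.id} has an empty CDS")

    seed_index: dict[bytes, list[int]] = {}
    for i, g in enumerate(genes):
        for km in set(kmer_positions(g.cds, k)):
            seed_index.setdefault(km, []).append(i)

    candidate: set[tuple[int, int]] = set()
    for idxs in seed_index.values():
        if len(idxs) < 2:
            continue
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                candidate.add((idxs[ai], idxs[bi]))

    scored: dict[int, list[AnchorPair]] = {}
    pairs: list[AnchorPair] = []
    for i, j in sorted(candidate):
        stats = align_stats(genes[i].cds, genes[j].cds)
        if stats.identity < min_identity:
            continue
        a, b = sorted((genes[i].id, genes[j].id))
        pairs.append(AnchorPair(a, b, stats.identity, stats.score))

    if max_hits_per_gene is not None:
        keep: set[AnchorPair] = set()
        per_gene: dict[str, list[AnchorPair]] = {}
        for p in pairs:
            per_gene.setdefault(p.gene_a, []).append(p)
            per_gene.setdefault(p.gene_b, []).append(p)
        for plist in per_gene.values():
            plist.sort(key=lambda p: (-p.score, p.gene_a, p.gene_b))
            keep.update(plist[:max_hits_per_gene])
        pairs = [p for p in pairs if p in keep]
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))


@dataclass
class SyntenyBlock:
    """A chained run of collinear anchor pairs linking two regions."""

    anchors: list[AnchorPair]
    contig_a: str
    contig_b: str
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    orientation: str  # "same" | "inverted"
    n_genes: int
    mean_identity: float = 0.0

    @property
    def span_a_length(self) -> int:
        return self.span_a[1] - self.span_a[0]

    @property
    def span_b_length(self) -> int:
        return self.span_b[1] - self.span_b[0]


def _collapse_tandem(pairs: list[AnchorPair], genes_by_id: dict[str, GeneModel],
                     tandem_ranks: int = 5) -> list[AnchorPair]:
    """Collapse tandem-array hits: for one gene, partners on the same contig
    within ``tandem_ranks`` ranks of each other keep only the best-scoring hit."""
    out: set[AnchorPair] = set(pairs)
    per_gene: dict[str, list[tuple[GeneModel, AnchorPair]]] = {}
    for p in pairs:
        per_gene.setdefault(p.gene_a, []).append((genes_by_id[p.gene_b], p))
        per_gene.setdefault(p.gene_b, []).append((genes_by_id[p.gene_a], p))
    for partners in per_gene.values():
        by_contig: dict[str, list[tuple[GeneModel, AnchorPair]]] = {}
        for gm, p in partners:
            by_contig.setdefault(gm.contig, []).append((gm, p))
        for plist in by_contig.values():
            plist.sort(key=lambda t: t[0].rank)
            cluster: list[tuple[GeneModel, AnchorPair]] = []
            for gm, p in plist + [(None, None)]:
                if cluster and (gm is None or gm.rank - cluster[-1][0].rank > tandem_ranks):
                    if len(cluster) > 1:
                        best = max(cluster, key=lambda t: t[1].score)[1]
                        for _, q in cluster:
                            if q is not best:
                                out.discard(q)
                    cluster = []
                if gm is not None:
                    cluster.append((gm, p))
    return [p for p in pairs if p in out]


def chain_collinear(anchors: list[AnchorPair], genes: list[GeneModel],
                    min_genes: int = 5, max_gap_genes: int = 10,
                    collapse_tandem: bool = True) -> list[SyntenyBlock]:
    """Chain anchor pairs into collinear blocks per contig pair.

    Best-first greedy extraction of the highest-weight chain (weight = anchor
    count, ties by score then by earlier contig_a rank); used anchors are
    removed and extraction repeats until no chain reaches ``min_genes``.
    """
    genes_by_id = {g.id: g for g in genes}
    if any(g.rank < 0 for g in genes_by_id.values()):
        assign_ranks(list(genes_by_id.values()))
    if collapse_tandem:
        anchors = _collapse_tandem(anchors, genes_by_id)

    groups: dict[tuple[str, str], list[tuple[int, int, AnchorPair, str, str]]] = {}
    for p in anchors:
        ga, gb = genes_by_id[p.gene_a], genes_by_id[p.gene_b]
        if (ga.contig, ga.rank) > (gb.contig, gb.rank):
            ga, gb = gb, ga
        groups.setdefault((ga.contig, gb.contig), []).append(
            (ga.rank, gb.rank, p, ga.id, gb.id))

    blocks: list[SyntenyBlock] = []
    for (ca, cb), items in sorted(groups.items()):
        pool = sorted(items)
        while True:
            chain, orientation = _best_chain(pool, max_gap_genes)
            if len(chain) < min_genes:
                break
            used = set(id(pool[i]) for i in chain)
            members = [pool[i] for i in chain]
            pool = [it for it in pool if id(it) not in used]
            blocks.append(_make_block(members, ca, cb, orientation, genes_by_id))
    return blocks


def _best_chain(items: list, max_gap: int) -> tuple[list[int], str]:
    """Highest-weight strictly-monotone chain (both orientations tried)."""
    n = len(items)
    best: tuple[int, int, list[int], str] = (0, 0, [], "same")
    for orientation in ("same", "inverted"):
        sign = 1 if orientation == "same" else -1
        dp = [1] * n
        score = [items[i][2].score for i in range(n)]
        parent = [-1] * n
        for i in range(n):
            ra_i, rb_i = items[i][0], items[i][1]
            for j in range(i):
                ra_j, rb_j = items[j][0], items[j][1]
                if ra_j >= ra_i or ra_i - ra_j - 1 > max_gap:
                    continue
                db = sign * (rb_i - rb_j)
                if db <= 0 or db - 1 > max_gap:
                    continue
                cand = dp[j] + 1
                cand_score = score[j] + items[i][2].score
                if cand > dp[i] or (cand == dp[i] and cand_score > score[i]):
                    dp[i], score[i], parent[i] = cand, cand_score, j
        if n:
            i_best = max(range(n), key=lambda i: (dp[i], score[i], -items[i][0]))
            if (dp[i_best], score[i_best]) > (best[0], best[1]):
                chain = []
                i = i_best
                while i != -1:
                    chain.append(i)
                    i = parent[i]
                best = (dp[i_best], score[i_best], chain[::-1], orientation)
    return best[2], best[3]


def _make_block(members, ca, cb, orientation, genes_by_id) -> SyntenyBlock:
    pairs = [m[2] for m in members]
    ga = [genes_by_id[m[3]] for m in members]
    gb = [genes_by_id[m[4]] for m in members]
    return SyntenyBlock(
        anchors=pairs, contig_a=ca, contig_b=cb,
        span_a=(min(g.start for g in ga), max(g.end for g in ga)),
        span_b=(min(g.start for g in gb), max(g.end for g in gb)),
        orientation=orientation, n_genes=len(pairs),
        mean_identity=sum(p.identity for p in pairs) / len(pairs))


def pair_haplotype_blocks(blocks: list[SyntenyBlock],
                          min_span: int = 75_000) -> list[SyntenyBlock]:
    """High-confidence haplotype candidates: both spans >= min_span, mirrors deduplicated."""
    seen: set[frozenset] = set()
    out: list[SyntenyBlock] = []
    for b in sorted(blocks, key=lambda b: (-b.n_genes, b.contig_a, b.span_a)):
        if b.span_a_length < min_span or b.span_b_length < min_span:
            continue
        key = frozenset([(b.contig_a, b.span_a), (b.contig_b, b.span_b)])
        if key in seen:
            continue
        seen.add(key)
        out.append(b)
    return out
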
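"""Synthetic diploid genome with fully known ground truth.

The generator builds, stage by stage, a small heterozygous genome that mimics
the statistical structure of a compact, LTR-purging plant genome:

1. :func:`generate_ancestral` — a haploid ancestor per contig: gene islands
   (random-codon CDS separated by ~1.1 kb intergenic gaps) interleaved with
   repeat-dense blocks reserved for transposable elements.
2. :func:`plant_ltr_elements` — intact LTR retrotransposons copied from a small
   family library, each inserted with a 5 bp target-site duplication; the two
   LTRs of an element are mutated independently with per-base probability
   mu * T so their expected pairwise divergence is 2 mu T for a planted age T.
3. :func:`form_solo_ltrs` — unequal-recombination events: for a configurable
   fraction of elements the internal region plus one LTR is deleted, leaving a
   solo LTR flanked by the original target-site duplication.
4. :func:`derive_haplotypes` — haplotype B is haplotype A plus random
   substitutions (98.2% identity by default, sparing the dated LTR spans) and
   large haplotype-specific insertions planted into one haplotype only, each
   assembled to an LTR-rich / gene-poor composition target.
5. :func:`simulate_methylome` — per-cytosine bisulfite counts with
   context-specific true levels (no gene-body methylation, high CpG/CHG on LTR
   bodies with levels ramping down across 1 kb flanks).
6. :func:`simulate_expression` — a TPM table in which most indel-region genes
   are transcriptionally silent (TPM < 0.5).

Every stage records exact ground truth (ages, breakpoints, compositions,
levels) so downstream callers can be scored for recall, precision and
parameter recovery. Identical configs (including seed) give byte-identical
output.

Internally all coordinates are 0-based half-open; GFF3 output converts to
1-based inclusive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from haplodyn.config import AgeDistribution, ConfigError, SimulationConfig, SizingError

# ---------------------------------------------------------------------------
# sequence helpers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_STOPS = {b"TAA", b"TAG", b"TGA"}
_CODONS = [bytes((a, b, c)) for a in b"ACGT" for b in b"ACGT" for c in b"ACGT"]
_SENSE_CODONS = np.array([list(c) for c in _CODONS if c not in _STOPS], dtype=np.uint8)

_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def random_dna(rng: np.random.Generator, n: int) -> bytes:
    return _BASES[rng.integers(0, 4, size=n)].tobytes()


def random_cds(rng: np.random.Generator, n_codons: int) -> bytes:
    """ATG + (n_codons - 2) random sense codons + TAA."""
    body = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS), size=max(0, n_codons - 2))]
    return b"ATG" + body.tobytes() + b"TAA"


def mutate(seq: bytes, rng: np.random.Generator, p: float,
           exclude: list[tuple[int, int]] | None = None) -> tuple[bytes, int]:
    """Substitute each base independently with probability ``p``.

    Substitutions always change the base (uniform over the three others).
    ``exclude`` intervals (0-based half-open) are left untouched.
    Returns (mutated sequence, number of substitutions).
    """
    if p < 0 or p > 1:
        raise ConfigError(f"substitution probability must be in [0,1], got {p}")
    arr = np.frombuffer(seq, dtype=np.uint8).copy()
    hit = rng.random(arr.size) < p
    if exclude:
        for s, e in exclude:
            hit[max(0, s):max(0, e)] = False
    pos = np.flatnonzero(hit)
    if pos.size:
        codes = _CODE[arr[pos]]
        arr[pos] = _BASES[(codes + rng.integers(1, 4, size=pos.size)) % 4]
    return arr.tobytes(), int(pos.size)


def revcomp(seq: bytes) -> bytes:
    return _COMP[np.frombuffer(seq, dtype=np.uint8)][::-1].tobytes()


# ---------------------------------------------------------------------------
# coordinate remapping under insertions / deletions


def _interval_mapper(positions: np.ndarray, deltas: np.ndarray):
    """Mapper for feature intervals under edits at ``positions``.

    ``deltas`` are signed length changes applied *at* each position (insertions
    positive, deletions negative; deletion coordinates are given at the
    deletion start after the deleted span has been conceptually collapsed).
    An edit at a feature's start shifts the whole feature; an edit at its end
    leaves it alone.
    """
    cum = np.concatenate([[0], np.cumsum(deltas)])

    def map_point(c: int, side: str = "right") -> int:
        idx = int(np.searchsorted(positions, c, side=side))
        return int(c + cum[idx])

    def map_interval(s: int, e: int) -> tuple[int, int]:
        return map_point(s, "right"), map_point(e, "left")

    return map_point, map_interval


def apply_insertions(seq: bytes, insertions: list[tuple[int, bytes]]):
    """Insert payloads into ``seq`` at the given original coordinates.

    Returns (new_seq, map_point, map_interval). Positions must be distinct.
    """
    ins = sorted(insertions, key=lambda t: t[0])
    parts: list[bytes] = []
    prev = 0
    for pos, payload in ins:
        parts.append(seq[prev:pos])
        parts.append(payload)
        prev = pos
    parts.append(seq[prev:])
    positions = np.array([p for p, _ in ins], dtype=np.int64)
    deltas = np.array([len(s) for _, s in ins], dtype=np.int64)
    mp, mi = _interval_mapper(positions, deltas)
    return b"".join(parts), mp, mi


def apply_deletions(seq: bytes, spans: list[tuple[int, int]]):
    """Delete the given disjoint spans. Returns (new_seq, map_point, map_interval)."""
    spans = sorted(spans)
    parts: list[bytes] = []
    prev = 0
    for s, e in spans:
        if s < prev:
            raise ValueError("deletion spans must be disjoint and sorted")
        parts.append(seq[prev:s])
        prev = e
    parts.append(seq[prev:])
    positions = np.array([s for s, _ in spans], dtype=np.int64)
    deltas = np.array([-(e - s) for s, e in spans], dtype=np.int64)
    # a point at or beyond a deletion start maps back to the deletion start
    cum = np.concatenate([[0], np.cumsum(deltas)])
    ends = np.array([e for _, e in spans], dtype=np.int64)

    def map_point(c: int, side: str = "right") -> int:
        idx = int(np.searchsorted(ends, c, side="left"))
        base = int(c + cum[idx])
        if idx < len(positions) and c > positions[idx]:  # inside deleted span
            base = int(positions[idx] + cum[idx])
        return base

    def map_interval(s: int, e: int) -> tuple[int, int]:
        return map_point(s), map_point(e)

    return b"".join(parts), map_point, map_interval


# ---------------------------------------------------------------------------
# truth records


@dataclass
class GeneRecord:
    id: str
    contig: str
    start: int
    end: int
    strand: str
    cds: bytes
    in_indel: bool = False


@dataclass
class LTRTruth:
    id: str
    contig: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    family: str
    superfamily: str
    age: float
    in_indel: bool = False


@dataclass
class SoloTruth:
    id: str
    contig: str
    start: int
    end: int
    family: str


@dataclass
class IndelTruth:
    id: str
    contig: str          # base contig name
    carrier: str         # "A" or "B"
    start: int           # carrier-haplotype coordinates
    end: int
    size: int
    ltr_bp: int
    gene_bp: int
    other_bp: int


@dataclass(frozen=True)
class LTRFamilyTemplate:
    name: str
    superfamily: str
    ltr: bytes
    internal: bytes

    @property
    def element(self) -> bytes:
        return self.ltr + self.internal + self.ltr

    @property
    def length(self) -> int:
        return 2 * len(self.ltr) + len(self.internal)


@dataclass
class GenomeTruth:
    """The synthetic genome plus every planted ground-truth record."""

    config: SimulationConfig
    contigs: list[str] = field(default_factory=list)
    seqs: dict[str, bytes] = field(default_factory=dict)          # base (pre-haplotype)
    genes: list[GeneRecord] = field(default_factory=list)          # base coords
    repeat_blocks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    library: list[LTRFamilyTemplate] = field(default_factory=list)
    elements: list[LTRTruth] = field(default_factory=list)         # base coords
    solos: list[SoloTruth] = field(default_factory=list)           # base coords
    # filled by derive_haplotypes (haplotype coordinates, contig names *_A/*_B)
    hap_seqs: dict[str, bytes] = field(default_factory=dict)
    genes_hap: list[GeneRecord] = field(default_factory=list)
    elements_hap: list[LTRTruth] = field(default_factory=list)
    solos_hap: list[SoloTruth] = field(default_factory=list)
    indels: list[IndelTruth] = field(default_factory=list)
    n_snps: int = 0
    snp_eligible_bp: int = 0
    methylation_truth: pd.DataFrame | None = None
    methylomes: list[pd.DataFrame] = field(default_factory=list)
    expression: pd.DataFrame | None = None

    def hap_name(self, contig: str, hap: str) -> str:
        return f"{contig}_{hap}"


def _rng_for(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[stage])


# ---------------------------------------------------------------------------
# stage 1: ancestral haploid genome


def generate_ancestral(config: SimulationConfig) -> GenomeTruth:
    """Build the haploid ancestor: gene islands separated by repeat-dense blocks."""
    config.validate()
    rng = _rng_for(config, 0)
    genome = GenomeTruth(config=config)

    lo_c, hi_c = config.gene_codon_range
    mean_gene = 3 * (lo_c + hi_c) / 2
    gene_counter = 0
    for ci in range(config.n_contigs):
        name = f"contig{ci + 1}"
        L = config.contig_length
        n_genes = int(round(L * config.gene_density))
        min_needed = n_genes * (3 * lo_c + 6 + 150)
        if min_needed > L:
            raise SizingError(
                f"{n_genes} genes need >= {min_needed} bp but contig length is {L} bp; "
                "lower gene_density or raise contig_length"
            )
        gene_gap_bp = int(n_genes * (mean_gene + config.intergenic_mean))
        repeat_total = max(2000, L - gene_gap_bp)
        n_islands = max(1, int(round(n_genes / config.island_size)))
        block_lens = rng.multinomial(repeat_total, np.full(n_islands + 1, 1.0 / (n_islands + 1)))
        island_sizes = rng.multinomial(n_genes, np.full(n_islands, 1.0 / n_islands))

        parts: list[bytes] = []
        cursor = 0
        blocks: list[tuple[int, int]] = []
        for isl in range(n_islands):
            blen = int(block_lens[isl])
            if blen > 0:
                parts.append(random_dna(rng, blen))
                blocks.append((cursor, cursor + blen))
                cursor += blen
            for _ in range(int(island_sizes[isl])):
                gap = max(150, int(rng.normal(config.intergenic_mean, config.intergenic_mean * 0.3)))
                parts.append(random_dna(rng, gap))
                cursor += gap
                codons = int(rng.integers(lo_c, hi_c + 1))
                cds = random_cds(rng, codons)
                strand = "+" if rng.random() < 0.5 else "-"
                gene_counter += 1
                genome.genes.append(GeneRecord(
                    id=f"g{gene_counter:05d}", contig=name, start=cursor,
                    end=cursor + len(cds), strand=strand,
                    cds=cds if strand == "+" else revcomp(cds)))
                parts.append(cds if strand == "+" else revcomp(cds))
                cursor += len(cds)
        blen = int(block_lens[-1])
        if blen > 0:
            parts.append(random_dna(rng, blen))
            blocks.append((cursor, cursor + blen))
            cursor += blen
        genome.contigs.append(name)
        genome.seqs[name] = b"".join(parts)
        genome.repeat_blocks[name] = blocks

    # genes store the *coding-strand* CDS; re-read from genome for minus strand
    for g in genome.genes:
        span = genome.seqs[g.contig][g.start:g.end]
        g.cds = span if g.strand == "+" else revcomp(span)
    return genome


# ---------------------------------------------------------------------------
# stage 2: LTR family library and intact-element planting


def default_ltr_library(seed: int = 0) -> list[LTRFamilyTemplate]:
    """Two LTR-RT families with distinct LTR lengths (TG...CA termini).

    Gypsy-like elements dominate compact purging genomes; the Copia-like family
    is smaller with a shorter LTR.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(8)[7])

    def make_ltr(n: int) -> bytes:
        return b"TG" + random_dna(rng, n - 4) + b"CA"

    return [
        LTRFamilyTemplate("Gypsy-1", "Gypsy", make_ltr(3500), random_dna(rng, 4000)),
        LTRFamilyTemplate("Copia-1", "Copia", make_ltr(1000), random_dna(rng, 1500)),
    ]


def _mutated_element(template: LTRFamilyTemplate, age: float, mu: float,
                     rng: np.random.Generator) -> tuple[bytes, int]:
    """Template copy aged ``age`` years: both LTRs mutated independently at mu*T."""
    p = mu * age
    if p >= 0.75:
        raise ConfigError(
            f"mu*T = {p:.3f} >= 0.75: divergence saturates and the age is "
            "Jukes-Cantor-unrecoverable; refuse to plant")
    ltr5, _ = mutate(template.ltr, rng, p)
    ltr3, _ = mutate(template.ltr, rng, p)
    internal, _ = mutate(template.internal, rng, p)
    return ltr5 + internal + ltr3, len(template.ltr)


def _pick_sites(rng: np.random.Generator, intervals: list[tuple[int, int]],
                n: int, min_gap: int, taken: list[int] | None = None) -> list[int]:
    """Sample ``n`` points inside ``intervals``, pairwise >= min_gap apart."""
    if not intervals:
        raise SizingError("no candidate intervals to place features in")
    lens = np.array([e - s for s, e in intervals], dtype=float)
    starts = [s for s, _ in intervals]
    chosen: list[int] = list(taken or [])
    out: list[int] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > 200 * max(n, 1):
            raise SizingError(
                f"could not place {n} features with {min_gap} bp separation; "
                "repeat blocks too small for the requested element count")
        i = rng.choice(len(intervals), p=lens / lens.sum())
        pos = int(starts[i] + rng.integers(0, int(lens[i])))
        if all(abs(pos - c) >= min_gap for c in chosen):
            chosen.append(pos)
            out.append(pos)
    return sorted(out)


def plant_ltr_elements(genome: GenomeTruth, config: SimulationConfig | None = None,
                       library: list[LTRFamilyTemplate] | None = None) -> GenomeTruth:
    """Insert intact LTR elements of known age into the repeat blocks."""
    config = config or genome.config
    if not genome.seqs:
        raise ConfigError("ancestral genome must be generated first")
    rng = _rng_for(config, 1)
    genome.library = library or default_ltr_library(config.seed)
    tsd = config.tsd_length

    n = config.n_intact_ltr
    ages = config.ltr_age_distribution.sample(rng, n)
    fams = rng.choice(len(genome.library), size=n, p=_family_weights(genome.library))
    # distribute elements across contigs proportionally to repeat-block space
    weights = np.array([sum(e - s for s, e in genome.repeat_blocks[c]) for c in genome.contigs],
                       dtype=float)
    counts = rng.multinomial(n, weights / weights.sum())
    eid = 0
    for c, n_c in zip(genome.contigs, counts):
        if n_c == 0:
            continue
        margin = 50
        cand = [(s + margin, e - margin) for s, e in genome.repeat_blocks[c]
                if e - s > 2 * margin + 10]
        sites = _pick_sites(rng, cand, int(n_c), min_gap=400)
        insertions = []
        meta = []
        seq = genome.seqs[c]
        for pos in sites:
            template = genome.library[int(fams[eid])]
            age = float(ages[eid])
            elem, ltr_len = _mutated_element(template, age, config.mu, rng)
            tsd_seq = seq[pos:pos + tsd]
            insertions.append((pos + tsd, elem + tsd_seq))
            meta.append((pos + tsd, len(elem), ltr_len, template, age))
            eid += 1
        new_seq, map_point, map_interval = apply_insertions(seq, insertions)
        genome.seqs[c] = new_seq
        _remap_contig_features(genome, c, map_interval)
        for pos, elen, ltr_len, template, age in meta:
            # the payload inserted at pos begins at pos shifted by insertions
            # strictly before it (side="left" excludes the payload itself)
            s = map_point(pos, "left")
            genome.elements.append(LTRTruth(
                id=f"LTR{len(genome.elements) + 1:04d}", contig=c,
                start=s, end=s + elen,
                ltr5=(s, s + ltr_len), ltr3=(s + elen - ltr_len, s + elen),
                family=template.name, superfamily=template.superfamily, age=age))
    return genome


def _family_weights(library: list[LTRFamilyTemplate]) -> np.ndarray:
    """Strongly Gypsy-dominated family mix (Gypsy:Copia intact counts ~ 33:1),
    matching the classified intact population of a compact purging genome."""
    w = np.array([33.0 if t.superfamily == "Gypsy" else 1.0 for t in library])
    return w / w.sum()


def _remap_contig_features(genome: GenomeTruth, contig: str, map_interval) -> None:
    for g in genome.genes:
        if g.contig == contig:
            g.start, g.end = map_interval(g.start, g.end)
    for el in genome.elements:
        if el.contig == contig:
            el.start, el.end = map_interval(el.start, el.end)
            el.ltr5 = map_interval(*el.ltr5)
            el.ltr3 = map_interval(*el.ltr3)
    for so in genome.solos:
        if so.contig == contig:
            so.start, so.end = map_interval(so.start, so.end)
    genome.repeat_blocks[contig] = [map_interval(s, e) for s, e in genome.repeat_blocks[contig]]


# ---------------------------------------------------------------------------
# stage 3: solo-LTR formation


def form_solo_ltrs(genome: GenomeTruth, config: SimulationConfig | None = None) -> GenomeTruth:
    """Unequal recombination: delete internal region + one LTR for a subset."""
    config = config or genome.config
    if not 0.0 <= config.solo_fraction <= 1.0:
        raise ConfigError(f"solo_fraction must be in [0,1], got {config.solo_fraction}")
    if not genome.elements:
        if config.solo_fraction > 0 and config.n_intact_ltr > 0:
            raise ConfigError("intact elements must be planted before solo formation")
        return genome
    rng = _rng_for(config, 2)
    n_solo = int(round(config.solo_fraction * len(genome.elements)))
    chosen_idx = rng.choice(len(genome.elements), size=n_solo, replace=False)
    chosen_ids = {genome.elements[int(i)].id for i in chosen_idx}

    for contig in genome.contigs:
        victims = [el for el in genome.elements
                   if el.contig == contig and el.id in chosen_ids]
        if not victims:
            continue
        spans = [(el.ltr5[1], el.end) for el in victims]  # keep the 5' LTR
        new_seq, _, map_interval = apply_deletions(genome.seqs[contig], spans)
        genome.seqs[contig] = new_seq
        solo_new = [SoloTruth(id=el.id.replace("LTR", "SOLO"), contig=contig,
                              start=map_interval(*el.ltr5)[0],
                              end=map_interval(*el.ltr5)[1], family=el.family)
                    for el in victims]
        _remap_contig_features(genome, contig, map_interval)
        genome.solos.extend(solo_new)  # already in post-deletion coordinates
    genome.elements = [el for el in genome.elements if el.id not in chosen_ids]
    return genome


# ---------------------------------------------------------------------------
# stage 4: haplotype derivation with planted indels


def _assemble_indel_segment(size: int, config: SimulationConfig,
                            library: list[LTRFamilyTemplate],
                            rng: np.random.Generator,
                            ids: dict[str, int]):
    """Build one haplotype-specific segment hitting the composition targets.

    Returns (segment bytes, element records, gene records) with coordinates
    relative to the segment start.
    """
    target_ltr = config.indel_ltr_fraction * size
    target_gene = config.indel_gene_fraction * size
    tsd = config.tsd_length

    # choose element counts per family minimizing |ltr_bp - target| under the
    # constraint that everything (plus genes and some filler) fits
    lens = [t.length for t in library]
    best, best_err = (0,) * len(library), target_ltr
    max_counts = [int(target_ltr // l) + 1 for l in lens]
    from itertools import product
    for combo in product(*[range(m + 1) for m in max_counts]):
        bp = sum(c * l for c, l in zip(combo, lens))
        if bp + target_gene + 200 > size:
            continue
        err = abs(bp - target_ltr)
        if err < best_err:
            best, best_err = combo, err
    element_templates: list[LTRFamilyTemplate] = []
    for c, t in zip(best, library):
        element_templates.extend([t] * c)
    rng.shuffle(element_templates)

    mean_gene = 3 * sum(config.gene_codon_range) / 2
    n_genes = int(round(target_gene / mean_gene))
    gene_seqs = []
    for _ in range(n_genes):
        codons = int(rng.integers(*config.gene_codon_range))
        gene_seqs.append(random_cds(rng, codons))

    ages = config.indel_ltr_age_distribution.sample(rng, len(element_templates))
    pieces: list[tuple[str, bytes, object]] = []   # (kind, seq, meta)
    for template, age in zip(element_templates, ages):
        elem, ltr_len = _mutated_element(template, float(age), config.mu, rng)
        t = random_dna(rng, tsd)
        pieces.append(("element", t + elem + t, (template, float(age), ltr_len, len(t))))
    for cds in gene_seqs:
        strand = "+" if rng.random() < 0.5 else "-"
        pieces.append(("gene", cds if strand == "+" else revcomp(cds), (cds, strand)))
    order = rng.permutation(len(pieces))
    pieces = [pieces[i] for i in order]

    used = sum(len(p[1]) for p in pieces)
    filler_total = size - used
    if filler_total < 0:
        raise SizingError(f"indel of {size} bp cannot hold its planted content ({used} bp)")
    cuts = rng.multinomial(filler_total, np.full(len(pieces) + 1, 1.0 / (len(pieces) + 1)))

    parts: list[bytes] = []
    cursor = 0
    elements: list[LTRTruth] = []
    genes: list[GeneRecord] = []
    for i, (kind, seqpiece, meta) in enumerate(pieces):
        f = int(cuts[i])
        parts.append(random_dna(rng, f))
        cursor += f
        if kind == "element":
            template, age, ltr_len, tlen = meta
            s = cursor + tlen
            e = s + len(seqpiece) - 2 * tlen
            ids["ltr"] += 1
            elements.append(LTRTruth(
                id=f"LTRI{ids['ltr']:04d}", contig="", start=s, end=e,
                ltr5=(s, s + ltr_len), ltr3=(e - ltr_len, e),
                family=template.name, superfamily=template.superfamily,
                age=age, in_indel=True))
        else:
            cds, strand = meta
            ids["gene"] += 1
            genes.append(GeneRecord(
                id=f"gi{ids['gene']:04d}", contig="", start=cursor,
                end=cursor + len(seqpiece), strand=strand, cds=cds, in_indel=True))
        parts.append(seqpiece)
        cursor += len(seqpiece)
    parts.append(random_dna(rng, int(cuts[-1])))
    segment = b"".join(parts)
    assert len(segment) == size
    ltr_bp = sum(e.end - e.start for e in elements)
    gene_bp = sum(g.end - g.start for g in genes)
    return segment, elements, genes, ltr_bp, gene_bp


def derive_haplotypes(genome: GenomeTruth, config: SimulationConfig | None = None) -> GenomeTruth:
    """Produce haplotypes A and B: SNPs at snp_rate plus haplotype-specific indels."""
    config = config or genome.config
    if not genome.seqs:
        raise ConfigError("genome must be built before deriving haplotypes")
    rng = _rng_for(config, 3)

    # --- choose indel sizes / carriers / base positions
    lo, hi = config.indel_size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_planted_indels))
    sizes = sizes.astype(int)
    carriers = rng.choice(["A", "B"], size=config.n_planted_indels)
    contig_lens = np.array([len(genome.seqs[c]) for c in genome.contigs], dtype=float)
    indel_contigs = rng.choice(len(genome.contigs), size=config.n_planted_indels,
                               p=contig_lens / contig_lens.sum())

    total_indel = int(sizes.sum())
    if total_indel > sum(contig_lens):
        raise SizingError(
            f"requested {total_indel} bp of indels exceeds genome capacity")

    # forbidden zones: genes, elements, solos (+300 bp margin), contig ends
    # indel breakpoints need unique flanking sequence on both sides so the
    # caller's anchor model is identifiable: keep clear of genes and far from
    # repeat copies (which are anchor deserts)
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.contigs}
    for g in genome.genes:
        forbidden[g.contig].append((g.start - 300, g.end + 300))
    for el in genome.elements:
        forbidden[el.contig].append((el.start - 800, el.end + 800))
    for so in genome.solos:
        forbidden[so.contig].append((so.start - 800, so.end + 800))

    def free_position(contig: str, existing: list[int]) -> int:
        L = len(genome.seqs[contig])
        zones = sorted(forbidden[contig])
        for _ in range(5000):
            pos = int(rng.integers(2000, L - 2000))
            if any(s <= pos < e for s, e in zones):
                continue
            if any(abs(pos - q) < 2000 for q in existing):
                continue
            return pos
        raise SizingError(f"no free insertion site found on {contig}")

    ids = {"ltr": 0, "gene": 0}
    per_hap_ins: dict[str, dict[str, list]] = {
        "A": {c: [] for c in genome.contigs}, "B": {c: [] for c in genome.contigs}}
    chosen_pos: dict[str, list[int]] = {c: [] for c in genome.contigs}
    indel_meta = []
    for i in range(config.n_planted_indels):
        c = genome.contigs[int(indel_contigs[i])]
        pos = free_position(c, chosen_pos[c])
        chosen_pos[c].append(pos)
        seg, els, gs, ltr_bp, gene_bp = _assemble_indel_segment(
            int(sizes[i]), config, genome.library or default_ltr_library(config.seed),
            rng, ids)
        hap = str(carriers[i])
        per_hap_ins[hap][c].append((pos, seg, els, gs))
        indel_meta.append((i, c, hap, pos, int(sizes[i]), ltr_bp, gene_bp))

    # --- SNPs for haplotype B (sparing dated LTR spans of intact elements)
    snp_exclude: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.contigs}
    for el in genome.elements:
        snp_exclude[el.contig].extend([el.ltr5, el.ltr3])

    hapA_base = dict(genome.seqs)
    hapB_base = {}
    n_snps = 0
    eligible = 0
    for c in genome.contigs:
        seq_b, k = mutate(genome.seqs[c], rng, config.snp_rate, exclude=snp_exclude[c])
        hapB_base[c] = seq_b
        n_snps += k
        eligible += len(seq_b) - sum(e - s for s, e in snp_exclude[c])
    genome.n_snps = n_snps
    genome.snp_eligible_bp = eligible

    # --- apply insertions per haplotype and emit haplotype feature tables
    for hap, base in (("A", hapA_base), ("B", hapB_base)):
        for c in genome.contigs:
            hname = genome.hap_name(c, hap)
            ins = [(pos, seg) for pos, seg, _, _ in per_hap_ins[hap][c]]
            new_seq, map_point, map_interval = apply_insertions(base[c], ins)
            genome.hap_seqs[hname] = new_seq
            for g in genome.genes:
                if g.contig != c:
                    continue
                s, e = map_interval(g.start, g.end)
                cds = new_seq[s:e] if g.strand == "+" else revcomp(new_seq[s:e])
                genome.genes_hap.append(replace(g, id=f"{g.id}_{hap}", contig=hname,
                                                start=s, end=e, cds=cds))
            for el in genome.elements:
                if el.contig != c:
                    continue
                genome.elements_hap.append(replace(
                    el, id=f"{el.id}_{hap}", contig=hname,
                    start=map_interval(el.start, el.end)[0],
                    end=map_interval(el.start, el.end)[1],
                    ltr5=map_interval(*el.ltr5), ltr3=map_interval(*el.ltr3)))
            for so in genome.solos:
                if so.contig != c:
                    continue
                s, e = map_interval(so.start, so.end)
                genome.solos_hap.append(replace(so, id=f"{so.id}_{hap}",
                                                contig=hname, start=s, end=e))
            for pos, seg, els, gs in per_hap_ins[hap][c]:
                off = map_point(pos, "left")
                for el in els:
                    genome.elements_hap.append(replace(
                        el, contig=hname,
                        start=el.start + off, end=el.end + off,
                        ltr5=(el.ltr5[0] + off, el.ltr5[1] + off),
                        ltr3=(el.ltr3[0] + off, el.ltr3[1] + off)))
                for g in gs:
                    genome.genes_hap.append(replace(
                        g, contig=hname, start=g.start + off, end=g.end + off))

    # indel truth in carrier coordinates
    for i, c, hap, pos, size, ltr_bp, gene_bp in indel_meta:
        ins = [(p, seg) for p, seg, _, _ in per_hap_ins[hap][c]]
        _, map_point, _ = apply_insertions(hapA_base[c], ins)  # mapping only
        s = map_point(pos, "left")
        genome.indels.append(IndelTruth(
            id=f"IND{i + 1:03d}", contig=c, carrier=hap, start=s, end=s + size,
            size=size, ltr_bp=ltr_bp, gene_bp=gene_bp,
            other_bp=size - ltr_bp - gene_bp))
    return genome


# ---------------------------------------------------------------------------
# stage 5: methylome simulation


def cytosine_sites(seq: bytes) -> pd.DataFrame:
    """All cytosines of both strands with their CpG/CHG/CHH context.

    Context is read on the cytosine's own strand by the standard trinucleotide
    rule (CG -> CpG; CHG; CHH with H in {A,C,T}). Cytosines within 2 bp of a
    contig end, whose context is undefined, are dropped.
    """
    arr = np.frombuffer(seq, dtype=np.uint8)
    L = arr.size
    C, G = ord("C"), ord("G")
    fwd = np.flatnonzero(arr == C)
    fwd = fwd[(fwd >= 0) & (fwd < L - 2)]
    nxt1, nxt2 = arr[fwd + 1], arr[fwd + 2]
    ctx_f = np.where(nxt1 == G, 0, np.where(nxt2 == G, 1, 2))
    rev = np.flatnonzero(arr == G)
    rev = rev[rev >= 2]
    prv1, prv2 = arr[rev - 1], arr[rev - 2]
    ctx_r = np.where(prv1 == C, 0, np.where(prv2 == C, 1, 2))
    pos = np.concatenate([fwd, rev])
    strand = np.concatenate([np.zeros(fwd.size, dtype=np.uint8),
                             np.ones(rev.size, dtype=np.uint8)])
    ctx = np.concatenate([ctx_f, ctx_r])
    order = np.argsort(pos, kind="stable")
    names = np.array(["CpG", "CHG", "CHH"])
    return pd.DataFrame({
        "pos": pos[order],
        "strand": np.where(strand[order] == 0, "+", "-"),
        "context": names[ctx[order]],
    })


def _true_level_arrays(genome: GenomeTruth, contig_hap: str,
                       config: SimulationConfig, flank: int = 1000) -> dict[str, np.ndarray]:
    """Per-position true methylation level per context for one haplotype contig."""
    L = len(genome.hap_seqs[contig_hap])
    prof = config.methylation_profile
    out: dict[str, np.ndarray] = {}
    gene_spans = [(g.start, g.end) for g in genome.genes_hap if g.contig == contig_hap]
    ltr_spans = [(el.start, el.end) for el in genome.elements_hap if el.contig == contig_hap]
    ltr_spans += [(so.start, so.end) for so in genome.solos_hap if so.contig == contig_hap]
    for ctx in ("CpG", "CHG", "CHH"):
        bg = prof["background"][ctx]
        hi = prof["ltr_body"][ctx]
        lvl = np.full(L, bg)
        for s, e in gene_spans:
            lvl[max(0, s):e] = prof["gene_body"][ctx]
        for s, e in ltr_spans:
            # linear ramp from ~hi at the LTR edge down to bg at flank distance
            ls = max(0, s - flank)
            if s > ls:
                d = s - np.arange(ls, s)  # distance 1..flank from the edge
                lvl[ls:s] = np.maximum(lvl[ls:s], hi - (hi - bg) * d / flank)
            re_ = min(L, e + flank)
            if re_ > e:
                d = np.arange(e, re_) - e + 1
                lvl[e:re_] = np.maximum(lvl[e:re_], hi - (hi - bg) * d / flank)
        for s, e in ltr_spans:
            lvl[max(0, s):e] = hi
        out[ctx] = np.clip(lvl, 0.0, 1.0)
    return out


def simulate_methylome(genome: GenomeTruth, config: SimulationConfig | None = None) -> GenomeTruth:
    """Simulate per-cytosine bisulfite counts for each replicate (haplotype A).

    Coverage is Poisson(coverage_mean) per site and replicate; methylated
    counts are Binomial(coverage, true level). Sites with zero coverage are
    still reported (with 0/0 counts), as in a cytosine report.
    """
    config = config or genome.config
    if not genome.hap_seqs:
        raise ConfigError("haplotypes must be derived before simulating the methylome")
    rng = _rng_for(config, 4)
    frames_truth = []
    site_levels = []
    for c in genome.contigs:
        hname = genome.hap_name(c, "A")
        sites = cytosine_sites(genome.hap_seqs[hname])
        sites.insert(0, "contig", hname)
        levels = _true_level_arrays(genome, hname, config)
        lv = np.empty(len(sites))
        for ctx in ("CpG", "CHG", "CHH"):
            m = (sites["context"] == ctx).to_numpy()
            lv[m] = levels[ctx][sites["pos"].to_numpy()[m]]
        sites["true_level"] = lv
        frames_truth.append(sites)
        site_levels.append(lv)
    truth = pd.concat(frames_truth, ignore_index=True)
    genome.methylation_truth = truth
    all_levels = truth["true_level"].to_numpy()
    genome.methylomes = []
    for _ in range(config.n_replicates):
        cov = rng.poisson(config.coverage_mean, size=len(truth))
        meth = rng.binomial(cov, all_levels)
        rep = truth[["contig", "pos", "strand", "context"]].copy()
        rep["count_methylated"] = meth
        rep["count_unmethylated"] = cov - meth
        genome.methylomes.append(rep)
    return genome


# ---------------------------------------------------------------------------
# stage 6: expression simulation


def simulate_expression(genome: GenomeTruth, config: SimulationConfig | None = None) -> GenomeTruth:
    """Per-gene TPM: indel-region genes mostly silent, others broadly expressed.

    The monoploid gene set = ancestral genes + indel-planted genes. Indel genes
    are drawn from a silent/expressed mixture so that ``indel_gene_silent_fraction``
    of them fall below TPM 0.5 in expectation; the remaining genes absorb the
    normalization so the TPM column sums to exactly 1e6.
    """
    config = config or genome.config
    if not genome.indels and config.n_planted_indels > 0:
        raise ConfigError("haplotypes must be derived before simulating expression")
    rng = _rng_for(config, 5)
    base_ids = [g.id for g in genome.genes]
    indel_ids = sorted({g.id for g in genome.genes_hap if g.in_indel})
    n_i = len(indel_ids)
    silent = rng.random(n_i) < config.indel_gene_silent_fraction
    tpm_i = np.where(silent,
                     rng.uniform(0.0, 0.5, size=n_i),
                     0.5 + rng.lognormal(0.0, 1.0, size=n_i))
    raw = rng.lognormal(3.0, 1.2, size=len(base_ids))
    rest = 1e6 - tpm_i.sum()
    tpm_b = raw * (rest / raw.sum())
    genome.expression = pd.DataFrame({
        "gene_id": base_ids + indel_ids,
        "tpm": np.concatenate([tpm_b, tpm_i]),
        "in_indel": [False] * len(base_ids) + [True] * n_i,
    })
    return genome


# ---------------------------------------------------------------------------
# orchestration + fixture writing


def simulate_genome(config: SimulationConfig, methylome: bool = True,
                    expression: bool = True) -> GenomeTruth:
    """Run all simulation stages under one config."""
    genome = generate_ancestral(config)
    plant_ltr_elements(genome, config)
    form_solo_ltrs(genome, config)
    derive_haplotypes(genome, config)
    if methylome:
        simulate_methylome(genome, config)
    if expression:
        simulate_expression(genome, config)
    return genome


def _wrap_fasta(seq: bytes, width: int = 80) -> str:
    s = seq.decode("ascii")
    return "\n".join(s[i:i + width] for i in range(0, len(s), width))


def write_fixture(genome: GenomeTruth, directory: str | Path) -> dict:
    """Emit the fixture as plain-text files plus a checksum manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    for hap in ("A", "B"):
        p = d / f"haplotype_{hap}.fasta"
        with open(p, "w") as fh:
            for c in genome.contigs:
                hname = genome.hap_name(c, hap)
                fh.write(f">{hname}\n{_wrap_fasta(genome.hap_seqs[hname])}\n")
        files[f"haplotype_{hap}.fasta"] = p

    p = d / "genes.gff3"
    with open(p, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genome.genes_hap, key=lambda x: (x.contig, x.start)):
            a, b = g.start + 1, g.end
            fh.write(f"{g.contig}\thaplodyn\tgene\t{a}\t{b}\t.\t{g.strand}\t.\tID={g.id}\n")
            fh.write(f"{g.contig}\thaplodyn\tmRNA\t{a}\t{b}\t.\t{g.strand}\t.\t"
                     f"ID={g.id}.t1;Parent={g.id}\n")
            fh.write(f"{g.contig}\thaplodyn\tCDS\t{a}\t{b}\t.\t{g.strand}\t0\t"
                     f"ID={g.id}.cds;Parent={g.id}.t1\n")
    files["genes.gff3"] = p

    p = d / "ltr.gff3"
    with open(p, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in sorted(genome.elements_hap, key=lambda x: (x.contig, x.start)):
            fh.write(f"{el.contig}\thaplodyn\tLTR_retrotransposon\t{el.start + 1}\t{el.end}"
                     f"\t.\t+\t.\tID={el.id};family={el.family};superfamily={el.superfamily}\n")
            fh.write(f"{el.contig}\thaplodyn\tlong_terminal_repeat\t{el.ltr5[0] + 1}\t{el.ltr5[1]}"
                     f"\t.\t+\t.\tID={el.id}.ltr5;Parent={el.id}\n")
            fh.write(f"{el.contig}\thaplodyn\tlong_terminal_repeat\t{el.ltr3[0] + 1}\t{el.ltr3[1]}"
                     f"\t.\t+\t.\tID={el.id}.ltr3;Parent={el.id}\n")
        for so in sorted(genome.solos_hap, key=lambda x: (x.contig, x.start)):
            fh.write(f"{so.contig}\thaplodyn\tsolo_LTR\t{so.start + 1}\t{so.end}"
                     f"\t.\t+\t.\tID={so.id};family={so.family}\n")
    files["ltr.gff3"] = p

    p = d / "ltr_library.fasta"
    with open(p, "w") as fh:
        for t in genome.library:
            fh.write(f">{t.name}#LTR\n{_wrap_fasta(t.ltr)}\n")
            fh.write(f">{t.name}#INT\n{_wrap_fasta(t.internal)}\n")
    files["ltr_library.fasta"] = p

    pd.DataFrame([{
        "id": el.id, "contig": el.contig, "start": el.start, "end": el.end,
        "ltr5_start": el.ltr5[0], "ltr5_end": el.ltr5[1],
        "ltr3_start": el.ltr3[0], "ltr3_end": el.ltr3[1],
        "family": el.family, "superfamily": el.superfamily,
        "true_age_years": el.age, "in_indel": el.in_indel,
    } for el in genome.elements_hap]).to_csv(d / "truth_ltr_elements.tsv", sep="\t", index=False)
    files["truth_ltr_elements.tsv"] = d / "truth_ltr_elements.tsv"

    pd.DataFrame([{
        "id": so.id, "contig": so.contig, "start": so.start, "end": so.end,
        "family": so.family} for so in genome.solos_hap]
    ).to_csv(d / "truth_solo_ltrs.tsv", sep="\t", index=False)
    files["truth_solo_ltrs.tsv"] = d / "truth_solo_ltrs.tsv"

    pd.DataFrame([{
        "id": iv.id, "contig": iv.contig, "carrier": iv.carrier,
        "start": iv.start, "end": iv.end, "size": iv.size,
        "ltr_bp": iv.ltr_bp, "gene_bp": iv.gene_bp, "other_bp": iv.other_bp,
    } for iv in genome.indels]).to_csv(d / "truth_indels.tsv", sep="\t", index=False)
    files["truth_indels.tsv"] = d / "truth_indels.tsv"

    if genome.expression is not None:
        genome.expression.to_csv(d / "expression.tsv", sep="\t", index=False)
        files["expression.tsv"] = d / "expression.tsv"

    for i, rep in enumerate(genome.methylomes, start=1):
        p = d / f"cytosine_report_rep{i}.tsv"
        out = rep.copy()
        out["position"] = out.pop("pos") + 1  # 1-based in files
        out[["contig", "position", "strand", "count_methylated",
             "count_unmethylated", "context"]].to_csv(p, sep="\t", index=False)
        files[f"cytosine_report_rep{i}.tsv"] = p

    manifest = {"seed": genome.config.seed, "files": {}}
    for name, path in sorted(files.items()):
        h = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][name] = {"sha256": h, "bytes": path.stat().st_size}
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
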
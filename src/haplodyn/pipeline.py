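"""End-to-end experiments over the synthetic genome.

Thin orchestration used by the analysis drivers, the test suite and the
acceptance script: each function builds (or takes) a simulated genome, runs
one stage chain of the real pipeline, and scores the result against the
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from haplodyn import hapvar, ltr_dynamics, methylation_profiler as mp, stats_report, synteny
from haplodyn.config import AgeDistribution, SimulationConfig
from haplodyn.synthetic_data import GenomeTruth, simulate_genome


# ---------------------------------------------------------------------------
# truth -> pipeline input adapters


def gene_models_from_truth(genome: GenomeTruth) -> list[synteny.GeneModel]:
    models = [synteny.GeneModel(id=g.id, contig=g.contig, start=g.start, end=g.end,
                                strand=g.strand, cds=g.cds)
              for g in genome.genes_hap]
    return synteny.assign_ranks(models)


def elements_from_truth(genome: GenomeTruth, haplotype: str | None = None
                        ) -> list[ltr_dynamics.LTRElement]:
    out = []
    source = genome.elements_hap if genome.elements_hap else [
        # pre-haplotype stage: base coordinates
        e for e in genome.elements]
    for e in source:
        if haplotype and not e.contig.endswith(f"_{haplotype}"):
            if genome.elements_hap:
                continue
        out.append(ltr_dynamics.LTRElement(
            id=e.id, contig=e.contig, start=e.start, end=e.end,
            ltr5=e.ltr5, ltr3=e.ltr3, family=e.family, superfamily=e.superfamily))
    return out


def annotations_from_truth(genome: GenomeTruth):
    """(gene, LTR-related) annotation dicts keyed by haplotype contig."""
    gene_ann: dict[str, list] = {}
    ltr_ann: dict[str, list] = {}
    for c in genome.contigs:
        for hap in ("A", "B"):
            gene_ann[genome.hap_name(c, hap)] = []
            ltr_ann[genome.hap_name(c, hap)] = []
    for g in genome.genes_hap:
        gene_ann[g.contig].append((g.id, g.start, g.end))
    for e in genome.elements_hap:
        ltr_ann[e.contig].append((e.id, e.start, e.end))
    for s in genome.solos_hap:
        ltr_ann[s.contig].append((s.id, s.start, s.end))
    return gene_ann, ltr_ann


def library_entries(genome: GenomeTruth) -> list[tuple[str, str, bytes]]:
    out = []
    for t in genome.library:
        out.append((t.name, "LTR", t.ltr))
        out.append((t.name, "INT", t.internal))
    return out


# ---------------------------------------------------------------------------
# synteny + indel calling


def detect_haplotype_blocks(genome: GenomeTruth, min_identity: float = 0.90,
                            min_genes: int = 5, max_gap_genes: int = 10,
                            min_span: int = 75_000):
    models = gene_models_from_truth(genome)
    pairs = synteny.find_anchor_pairs(models, min_identity=min_identity)
    blocks = synteny.chain_collinear(pairs, models, min_genes=min_genes,
                                     max_gap_genes=max_gap_genes)
    return synteny.pair_haplotype_blocks(blocks, min_span=min_span), pairs, models


def call_haplotype_indels(genome: GenomeTruth, blocks=None,
                          k: int = 21, min_anchor: int = 100,
                          min_indel: int = 4000, max_partner_gap: int = 500):
    """Anchor-align each paired haplotype contig and call indels."""
    if blocks is None:
        blocks, _, _ = detect_haplotype_blocks(genome)
    pairs = sorted({(b.contig_a, b.contig_b) for b in blocks})
    calls, divergent = [], []
    for ca, cb in pairs:
        sa, sb = genome.hap_seqs[ca], genome.hap_seqs[cb]
        chain = hapvar.anchor_align(sa, sb, k=k, min_anchor=min_anchor)
        c, d = hapvar.call_indels(chain, sa, sb, min_indel=min_indel,
                                  max_partner_gap=max_partner_gap,
                                  contig_a=ca, contig_b=cb)
        calls.extend(c)
        divergent.extend(d)
    gene_ann, ltr_ann = annotations_from_truth(genome)
    flanks = []
    for call in calls:
        hapvar.classify_indel_content(call, gene_ann, ltr_ann)
        flanks.append(hapvar.summarize_flanks(
            call, gene_ann, ltr_ann,
            contig_length=len(genome.hap_seqs[call.contig_carrier])))
    return calls, flanks, divergent


def score_indel_calls(genome: GenomeTruth, calls) -> dict:
    """Recall / precision / boundary and size accuracy against planted truth."""
    truths = [(genome.hap_name(t.contig, t.carrier), t.start, t.end, t.size)
              for t in genome.indels]
    matched_t, matched_c = set(), set()
    boundary_errors, size_errors = [], []
    for ti, (tc, ts, te, tsize) in enumerate(truths):
        for ci, call in enumerate(calls):
            if call.contig_carrier != tc:
                continue
            ov = max(0, min(te, call.end) - max(ts, call.start))
            if ov >= 0.5 * tsize:
                matched_t.add(ti)
                matched_c.add(ci)
                boundary_errors.append(max(abs(call.start - ts), abs(call.end - te)))
                size_errors.append(abs(call.size - tsize))
    n_t, n_c = len(truths), len(calls)
    return {
        "n_truth": n_t, "n_calls": n_c,
        "recall": len(matched_t) / n_t if n_t else float("nan"),
        "precision": len(matched_c) / n_c if n_c else float("nan"),
        "max_boundary_error": float(max(boundary_errors)) if boundary_errors else float("nan"),
        "mean_boundary_error": float(np.mean(boundary_errors)) if boundary_errors else float("nan"),
        "max_size_error": float(max(size_errors)) if size_errors else float("nan"),
    }


# ---------------------------------------------------------------------------
# LTR dating / solo experiments


def age_recovery(seed: int, n_elements: int = 100,
                 contig_length: int = 1_000_000, n_contigs: int = 2) -> dict:
    """Plant elements with uniform ages on [0, 2 My] and recover them by dating."""
    cfg = SimulationConfig(
        seed=seed, n_contigs=n_contigs, contig_length=contig_length,
        n_intact_ltr=n_elements, solo_fraction=0.0, n_planted_indels=0,
        ltr_age_distribution=AgeDistribution(kind="uniform", min_age=0.0, max_age=2.0e6),
    ).validate()
    from haplodyn import synthetic_data as sd
    genome = sd.generate_ancestral(cfg)
    sd.plant_ltr_elements(genome, cfg)
    elements = elements_from_truth(genome)
    ltr_dynamics.date_elements(elements, genome.seqs, mu=cfg.mu)
    truth = {e.id: e.age for e in genome.elements}
    df = pd.DataFrame({
        "true_age": [truth[e.id] for e in elements],
        "est_age": [e.T for e in elements],
    }).dropna()
    fit = sstats.linregress(df["true_age"], df["est_age"])
    old = df[df["true_age"] >= 5.0e4]
    rel_err = (old["est_age"] - old["true_age"]).abs() / old["true_age"]
    return {
        "n": len(df), "slope": float(fit.slope), "intercept": float(fit.intercept),
        "r": float(fit.rvalue), "median_rel_err_ge50ky": float(rel_err.median()),
        "table": df,
    }


def solo_analysis(genome: GenomeTruth) -> dict:
    """Call solo LTRs from library hits and score against planted solos."""
    hits = ltr_dynamics.find_ltr_hits(genome.hap_seqs, library_entries(genome))
    solos = ltr_dynamics.call_solo_ltrs(hits)
    truth = [(s.contig, s.start, s.end) for s in genome.solos_hap]
    matched = 0
    for tc, ts, te in truth:
        for s in solos:
            if s.contig == tc and min(te, s.end) - max(ts, s.start) >= 0.5 * (te - ts):
                matched += 1
                break
    intact_spans = [(e.contig, e.start, e.end) for e in genome.elements_hap]
    false_on_intact = 0
    for s in solos:
        for tc, ts, te in intact_spans:
            if s.contig == tc and min(te, s.end) - max(ts, s.start) > 0:
                false_on_intact += 1
                break
    elements = elements_from_truth(genome)
    stats, aggregate, window = ltr_dynamics.solo_intact_ratio(elements, solos)
    return {"hits": hits, "solos": solos, "n_planted": len(truth),
            "n_called": len(solos), "n_matched": matched,
            "false_on_intact": false_on_intact,
            "family_stats": stats, "si_aggregate": aggregate,
            "length_window": window}


# ---------------------------------------------------------------------------
# methylation experiments


def methylation_analysis(genome: GenomeTruth, min_coverage: int = 3) -> dict:
    """Filter, average and profile the simulated methylomes; compare to truth."""
    reps = []
    total_cov = None
    for rep in genome.methylomes:
        lv, _ = mp.site_levels(rep, min_coverage=min_coverage)
        reps.append(lv)
        cov = rep["count_methylated"] + rep["count_unmethylated"]
        total_cov = cov if total_cov is None else total_cov + cov
    consensus = mp.average_replicates(reps)

    a_contigs = {genome.hap_name(c, "A") for c in genome.contigs}
    gene_feats = [mp.Feature(g.id, g.contig, g.start, g.end, g.strand)
                  for g in genome.genes_hap if g.contig in a_contigs]
    ltr_feats = [mp.Feature(e.id, e.contig, e.start, e.end, "+")
                 for e in genome.elements_hap if e.contig in a_contigs]

    profiles = {"gene": mp.metagene_profile(consensus, gene_feats, "gene"),
                "intact_LTR": mp.metagene_profile(consensus, ltr_feats, "intact_LTR")}

    truth_lv = genome.methylation_truth.rename(columns={"true_level": "level"})
    truth_profiles = {"gene": mp.metagene_profile(truth_lv, gene_feats, "gene"),
                      "intact_LTR": mp.metagene_profile(truth_lv, ltr_feats, "intact_LTR")}

    mean_cov = float(total_cov.mean()) if total_cov is not None else float("nan")
    rows = []
    for fc in profiles:
        for ctx in mp.CONTEXTS:
            obs, tru = profiles[fc][ctx], truth_profiles[fc][ctx]
            for (lab, m_obs, n), (_, m_tru, _) in zip(obs.bins, tru.bins):
                if n == 0 or np.isnan(m_obs) or np.isnan(m_tru):
                    continue
                se = np.sqrt(max(m_tru * (1 - m_tru), 1e-6) / max(n * mean_cov, 1.0))
                rows.append({"feature_class": fc, "context": ctx, "bin": lab,
                             "observed": m_obs, "truth": m_tru, "n_sites": n,
                             "se": se})
    recovery = pd.DataFrame(rows)
    if len(recovery):
        # simultaneous 99% binomial band over all bins (Bonferroni), with a
        # small absolute floor for bins whose sampling error is tiny
        z = sstats.norm.ppf(1 - 0.01 / (2 * len(recovery)))
        recovery["tol"] = np.maximum(z * recovery["se"], 0.01)

    gene_spans = {c: [] for c in a_contigs}
    ltr_spans = {c: [] for c in a_contigs}
    for f in gene_feats:
        gene_spans[f.contig].append((f.start, f.end))
    for f in ltr_feats:
        ltr_spans[f.contig].append((f.start, f.end))
    for s in genome.solos_hap:
        if s.contig in a_contigs:
            ltr_spans[s.contig].append((s.start, s.end))
    contig_lengths = {c: len(genome.hap_seqs[c]) for c in a_contigs}
    tracks, corr = mp.window_tracks(consensus, gene_spans, ltr_spans,
                                    contig_lengths, window=50_000)
    return {"consensus": consensus, "profiles": profiles,
            "truth_profiles": truth_profiles, "recovery": recovery,
            "tracks": tracks, "ltr_cpg_correlation": corr}


# ---------------------------------------------------------------------------
# full run


@dataclass
class FullRun:
    genome: GenomeTruth
    blocks: list
    calls: list
    flanks: list
    indel_score: dict
    composition: dict
    dated_elements: list
    n_saturated: int
    solo: dict
    enrichment: stats_report.EnrichmentResult
    methyl: dict
    expression: stats_report.ExpressionFilterResult


def full_analysis(seed: int, config: SimulationConfig | None = None,
                  methylome: bool = True) -> FullRun:
    """The whole chain on one simulated genome under the default study conditions."""
    cfg = (config or SimulationConfig(seed=seed)).validate()
    if cfg.seed != seed:
        cfg = cfg.with_(seed=seed)
    genome = simulate_genome(cfg, methylome=methylome, expression=True)

    blocks, _, _ = detect_haplotype_blocks(genome)
    calls, flanks, _ = call_haplotype_indels(genome, blocks)
    indel_score = score_indel_calls(genome, calls)
    composition = stats_report.composition_report(calls, flanks)

    elements = elements_from_truth(genome)
    dated, n_sat = ltr_dynamics.date_elements(elements, genome.hap_seqs, mu=cfg.mu)
    solo = solo_analysis(genome)

    indel_spans: dict[str, list[tuple[int, int]]] = {}
    for call in calls:
        indel_spans.setdefault(call.contig_carrier, []).append((call.start, call.end))
    enrichment = stats_report.young_ltr_enrichment(dated, indel_spans)

    methyl = methylation_analysis(genome) if methylome else {}

    indel_gene_ids = genome.expression.loc[genome.expression["in_indel"], "gene_id"]
    expr = stats_report.expression_filter(genome.expression, list(indel_gene_ids))

    return FullRun(genome=genome, blocks=blocks, calls=calls, flanks=flanks,
                   indel_score=indel_score, composition=composition,
                   dated_elements=dated, n_saturated=n_sat, solo=solo,
                   enrichment=enrichment, methyl=methyl, expression=expr)
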
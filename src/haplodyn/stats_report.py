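"""Statistics and reporting: rank-sum tests, enrichment, composition, RWC.

The workhorse is the Wilcoxon rank-sum (Mann-Whitney) test with mid-ranks for
ties. For small samples (n_x + n_y <= 20 by default) the null distribution of
the rank-sum W is enumerated exactly over all C(N, n_x) group assignments —
valid under ties, unlike the classical no-tie exact tables. Larger samples use
the normal approximation with tie-corrected variance and continuity
correction; a seeded permutation fallback is available.

Two-sided p-values are the default throughout; the two-sided exact/permutation
p is P(|W - E[W]| >= |w_obs - E[W]|), which is well defined with ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sstats

from haplodyn.config import ConfigError

EXACT_LIMIT = 20  # enumerate C(N, n_x) exactly up to this pooled size


@dataclass
class RankSumResult:
    statistic: float           # rank-sum W of sample x (mid-ranks)
    n_x: int
    n_y: int
    p_value: float
    method: str                # exact | normal_approximation | permutation
    alternative: str = "two-sided"


def _rank_sum_W(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)
    return float(ranks[: len(x)].sum()), ranks


def rank_sum_test(x, y, alternative: str = "two-sided", method: str = "auto",
                  n_permutations: int = 10_000, seed: int | None = None) -> RankSumResult:
    """Wilcoxon rank-sum test of two independent samples.

    ``alternative``: "two-sided", "greater" (x tends larger) or "less".
    ``method``: "auto" (exact when n_x + n_y <= 20, else normal),
    "exact", "normal_approximation", or "permutation" (seeded).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x < 1 or n_y < 1:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    N = n_x + n_y
    w_obs, ranks = _rank_sum_W(x, y)
    mu = n_x * (N + 1) / 2.0

    if np.ptp(np.concatenate([x, y])) == 0:
        warnings.warn("all values identical across both groups; p = 1")
        return RankSumResult(w_obs, n_x, n_y, 1.0, "degenerate", alternative)

    if method == "auto":
        method = "exact" if N <= EXACT_LIMIT else "normal_approximation"

    if method == "exact":
        perm_W = np.fromiter(
            (ranks[list(idx)].sum() for idx in combinations(range(N), n_x)),
            dtype=float)
        p = _tail_p(perm_W, w_obs, mu, alternative, plus_one=False)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        perm_W = np.empty(n_permutations)
        r = ranks.copy()
        for i in range(n_permutations):
            rng.shuffle(r)
            perm_W[i] = r[:n_x].sum()
        p = _tail_p(perm_W, w_obs, mu, alternative, plus_one=True)
    elif method == "normal_approximation":
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = (counts ** 3 - counts).sum() / (N * (N - 1))
        var = n_x * n_y / 12.0 * ((N + 1) - tie_term)
        sd = np.sqrt(var)
        if alternative == "two-sided":
            z = (abs(w_obs - mu) - 0.5) / sd
            p = min(1.0, 2.0 * sstats.norm.sf(z))
        elif alternative == "greater":
            p = sstats.norm.sf((w_obs - mu - 0.5) / sd)
        else:
            p = sstats.norm.cdf((w_obs - mu + 0.5) / sd)
        p = float(min(1.0, max(p, np.finfo(float).tiny)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return RankSumResult(w_obs, n_x, n_y, float(p), method, alternative)


def _tail_p(perm_W: np.ndarray, w_obs: float, mu: float, alternative: str,
            plus_one: bool) -> float:
    eps = 1e-9
    if alternative == "two-sided":
        extreme = np.abs(perm_W - mu) >= abs(w_obs - mu) - eps
    elif alternative == "greater":
        extreme = perm_W >= w_obs - eps
    else:
        extreme = perm_W <= w_obs + eps
    if plus_one:  # permutation estimate never returns 0
        return (extreme.sum() + 1) / (perm_W.size + 1)
    return extreme.sum() / perm_W.size


# ---------------------------------------------------------------------------
# young-LTR enrichment in haplotype-specific regions


@dataclass
class EnrichmentResult:
    n_inside: int
    n_outside: int
    proportion_young_in: float | None
    proportion_young_out: float | None
    young_cutoff: float
    rank_sum: RankSumResult | None
    flagged: bool = False      # True when a partition is empty


def young_ltr_enrichment(elements, indel_spans: dict[str, list[tuple[int, int]]],
                         young_cutoff: float = 1.0e5,
                         alternative: str = "two-sided",
                         seed: int | None = None) -> EnrichmentResult:
    """Are young elements (T < cutoff) over-represented inside indel regions?

    ``elements`` are dated LTR elements with genomic spans; an element is
    "inside" when >= 50% of its length overlaps an indel span on its contig.
    The rank-sum test compares insertion times inside vs outside (alternative
    "less": inside ages tend smaller).
    """
    t_in, t_out = [], []
    for el in elements:
        if not el.datable or el.T is None:
            continue
        length = el.end - el.start
        ov = sum(max(0, min(e, el.end) - max(s, el.start))
                 for s, e in indel_spans.get(el.contig, []))
        (t_in if ov >= 0.5 * length else t_out).append(el.T)
    if not t_in or not t_out:
        return EnrichmentResult(
            len(t_in), len(t_out),
            float(np.mean(np.array(t_in) < young_cutoff)) if t_in else None,
            float(np.mean(np.array(t_out) < young_cutoff)) if t_out else None,
            young_cutoff, None, flagged=True)
    rs = rank_sum_test(t_in, t_out, alternative=alternative, seed=seed)
    return EnrichmentResult(
        len(t_in), len(t_out),
        float(np.mean(np.array(t_in) < young_cutoff)),
        float(np.mean(np.array(t_out) < young_cutoff)),
        young_cutoff, rs)


# ---------------------------------------------------------------------------
# composition / expression / RWC / genome report


def composition_report(indel_calls, flank_records=None) -> dict:
    """bp-weighted aggregate composition of indel regions (and their flanks).

    ``indel_calls`` need ``size`` plus ``ltr_fraction``/``gene_fraction``/
    ``other_fraction``; ``flank_records`` are Composition-like with ``bp``.
    """
    def aggregate(items, get_bp, get):
        bp = np.array([get_bp(i) for i in items], dtype=float)
        if bp.sum() == 0:
            return {}
        return {k: float(np.sum(bp * np.array([get(i, k) for i in items])) / bp.sum())
                for k in ("ltr_fraction", "gene_fraction", "other_fraction")}

    out = {"n_indels": len(indel_calls),
           "indel_bp": int(sum(c.size for c in indel_calls)),
           "indel": aggregate(indel_calls, lambda c: c.size, getattr)}
    if flank_records is not None:
        out["flank"] = aggregate(flank_records, lambda f: f.bp, getattr)
    return out


@dataclass
class ExpressionFilterResult:
    n_total: int
    n_below: int
    fraction: float
    threshold: float
    missing_ids: list[str] = field(default_factory=list)


def expression_filter(tpm_table, gene_ids, threshold: float = 0.5) -> ExpressionFilterResult:
    """Count genes of ``gene_ids`` with TPM below ``threshold``.

    ``tpm_table`` is a mapping gene_id -> TPM or a DataFrame with ``gene_id``
    and ``tpm`` columns. Absent ids are reported and excluded from the
    denominator; an empty gene set is an error.
    """
    gene_ids = list(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene set")
    if hasattr(tpm_table, "set_index"):
        lookup = dict(zip(tpm_table["gene_id"], tpm_table["tpm"]))
    else:
        lookup = dict(tpm_table)
    missing = [g for g in gene_ids if g not in lookup]
    present = [g for g in gene_ids if g in lookup]
    if not present:
        raise ValueError("no supplied gene id is present in the TPM table")
    vals = np.array([lookup[g] for g in present], dtype=float)
    n_below = int((vals < threshold).sum())
    return ExpressionFilterResult(len(present), n_below, n_below / len(present),
                                  threshold, missing)


def relative_water_content(fw: float, dw: float, sw: float) -> float:
    """RWC = (FW - DW) / (SW - DW) with FW fresh, DW dry, SW saturated weight."""
    if sw <= dw:
        raise ValueError("saturated weight must exceed dry weight")
    if fw < dw:
        raise ValueError("fresh weight cannot be below dry weight")
    return (fw - dw) / (sw - dw)


def genome_summary(*, genome_size_bp: float, n_genes: int,
                   indel_sizes=None, collinear_bp: float | None = None,
                   elements=None, si_aggregate: float | None = None) -> dict:
    """Genome-level report: gene density, indel burden, element ages, S/I ratio.

    Rounding follows display conventions: densities and percentages to 1
    decimal, ratios to 2 decimals, ages to 2 significant figures in My.
    """
    out: dict = {
        "genome_size_bp": genome_size_bp,
        "n_genes": n_genes,
        "gene_density_kb_per_gene": round(genome_size_bp / n_genes / 1000.0, 1),
    }
    if indel_sizes is not None:
        sizes = np.asarray(list(indel_sizes), dtype=float)
        out["n_indels"] = int(sizes.size)
        out["indel_total_bp"] = float(sizes.sum())
        out["indel_min_bp"] = float(sizes.min()) if sizes.size else None
        out["indel_max_bp"] = float(sizes.max()) if sizes.size else None
        out["indel_mean_kb"] = round(float(sizes.mean()) / 1000.0) if sizes.size else None
        if collinear_bp:
            out["collinear_bp"] = float(collinear_bp)
            out["indel_percent_of_collinear"] = round(100.0 * sizes.sum() / collinear_bp, 1)
    if elements:
        per_sf: dict[str, list[float]] = {}
        for el in elements:
            if el.datable and el.T is not None:
                per_sf.setdefault(el.superfamily, []).append(el.T)
        out["superfamily"] = {
            sf: {"n": len(ts),
                 "mean_age_My": float(f"{np.mean(ts) / 1e6:.2g}")}
            for sf, ts in sorted(per_sf.items())}
    if si_aggregate is not None:
        out["solo_intact_ratio"] = round(si_aggregate, 2)
    return out
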
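"""Per-cytosine methylation levels, metagene profiles and landscape tracks.

Input is the per-cytosine report dialect (tab-separated: contig, 1-based
position, strand, count_methylated, count_unmethylated, context with context
in {CpG, CHG, CHH}). The level of a site is methylated / (methylated +
unmethylated); sites covered by fewer than ``min_coverage`` reads (default 3)
are removed. Replicates are averaged per site over the replicates in which the
site survived filtering (a site is kept if present in at least one replicate).

Metagene profiles pool site levels across features with equal per-site weight:
each feature body (TSS to TTS, or the LTR element span) is length-normalized
into ``n_body_bins`` bins, flanks (default 1 kb) are binned at fixed width,
and minus-strand features are flipped so upstream is always 5'. Symmetric CpG
sites are not merged across strands; every cytosine is its own record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

CONTEXTS = ("CpG", "CHG", "CHH")


class CytosineReportError(ValueError):
    """Malformed cytosine report record."""


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a cytosine report; positions converted to 0-based internally."""
    df = pd.read_csv(path, sep="\t")
    required = {"contig", "position", "strand", "count_methylated",
                "count_unmethylated", "context"}
    missing = required - set(df.columns)
    if missing:
        raise CytosineReportError(f"missing columns: {sorted(missing)}")
    bad = (df["count_methylated"] < 0) | (df["count_unmethylated"] < 0)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise CytosineReportError(f"negative count at line {line}")
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(df.index[bad_ctx][0]) + 2
        raise CytosineReportError(f"unknown context at line {line}")
    df = df.rename(columns={"position": "pos"})
    df["pos"] = df["pos"] - 1
    return df


def site_levels(records: pd.DataFrame, min_coverage: int = 3) -> tuple[pd.DataFrame, int]:
    """Per-site methylation level m/(m+u) for sites with coverage >= min_coverage.

    Returns (records with a ``level`` column, number of sites dropped).
    """
    total = records["count_methylated"] + records["count_unmethylated"]
    if (records["count_methylated"] > total).any():
        raise CytosineReportError("methylated count exceeds total")
    keep = total >= min_coverage
    out = records.loc[keep].copy()
    out["level"] = out["count_methylated"] / total[keep]
    return out, int((~keep).sum())


def average_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-site mean level over the replicates where the site passed filtering.

    A site is kept if present in >= 1 replicate. Input frames need ``contig``,
    ``pos``, ``strand``, ``context`` and ``level`` columns.
    """
    if not replicates:
        raise ValueError("at least one replicate is required")
    cat = pd.concat([r[["contig", "pos", "strand", "context", "level"]]
                     for r in replicates], ignore_index=True)
    out = (cat.groupby(["contig", "pos", "strand", "context"], sort=True,
                       observed=True)["level"]
           .agg(["mean", "size"]).reset_index()
           .rename(columns={"mean": "level", "size": "n_replicates"}))
    return out


@dataclass
class MetageneProfile:
    """Pooled mean methylation across features: flank / body / flank bins."""

    feature_class: str
    context: str
    bins: list[tuple[str, float, int]]     # (label, mean level, n sites)
    flank: int
    n_body_bins: int
    short_features: list[str] = field(default_factory=list)

    def bin_means(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.bins])


@dataclass(frozen=True)
class Feature:
    id: str
    contig: str
    start: int
    end: int
    strand: str = "+"


def metagene_profile(levels: pd.DataFrame, features: list[Feature],
                     feature_class: str = "gene", context: str | None = None,
                     flank: int = 1000, n_body_bins: int = 20,
                     flank_bin: int = 50) -> dict[str, MetageneProfile] | MetageneProfile:
    """Metagene profile(s) over ``features`` from filtered site levels.

    With ``context=None`` (default) one profile per context is returned as a
    dict; otherwise the single requested profile. Features shorter than
    ``n_body_bins`` bp contribute their body sites to the central body bin and
    are flagged in ``short_features``.
    """
    contexts = CONTEXTS if context is None else (context,)
    n_flank_bins = flank // flank_bin
    total_bins = 2 * n_flank_bins + n_body_bins

    by_contig: dict[str, pd.DataFrame] = {
        c: g.sort_values("pos") for c, g in levels.groupby("contig", observed=True)}
    sums = {ctx: np.zeros(total_bins) for ctx in contexts}
    counts = {ctx: np.zeros(total_bins, dtype=np.int64) for ctx in contexts}
    short: list[str] = []

    for f in features:
        sub = by_contig.get(f.contig)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, f.start - flank, side="left")
        hi = np.searchsorted(pos, f.end + flank, side="left")
        if hi <= lo:
            continue
        p = pos[lo:hi]
        lv = sub["level"].to_numpy()[lo:hi]
        ctx_arr = sub["context"].to_numpy()[lo:hi]
        body_len = f.end - f.start
        is_short = body_len < n_body_bins
        if is_short:
            short.append(f.id)
        bins = np.empty(p.size, dtype=np.int64)
        up = p < f.start
        down = p >= f.end
        body = ~(up | down)
        bins[up] = (p[up] - (f.start - flank)) // flank_bin
        if is_short:
            bins[body] = n_flank_bins + n_body_bins // 2
        else:
            bins[body] = n_flank_bins + (p[body] - f.start) * n_body_bins // body_len
        bins[down] = (n_flank_bins + n_body_bins
                      + (p[down] - f.end) // flank_bin)
        if f.strand == "-":
            bins = total_bins - 1 - bins
        for ctx in contexts:
            m = ctx_arr == ctx
            if m.any():
                np.add.at(sums[ctx], bins[m], lv[m])
                np.add.at(counts[ctx], bins[m], 1)

    labels = ([f"upstream_{i + 1}" for i in range(n_flank_bins)]
              + [f"body_{i + 1}" for i in range(n_body_bins)]
              + [f"downstream_{i + 1}" for i in range(n_flank_bins)])
    out: dict[str, MetageneProfile] = {}
    for ctx in contexts:
        with np.errstate(invalid="ignore"):
            means = sums[ctx] / counts[ctx]
        bins = [(lab, float(means[i]) if counts[ctx][i] else float("nan"),
                 int(counts[ctx][i])) for i, lab in enumerate(labels)]
        out[ctx] = MetageneProfile(feature_class, ctx, bins, flank, n_body_bins,
                                   short_features=list(short))
    return out if context is None else out[context]


def window_tracks(levels: pd.DataFrame,
                  gene_spans: dict[str, list[tuple[int, int]]],
                  ltr_spans: dict[str, list[tuple[int, int]]],
                  contig_lengths: dict[str, int],
                  window: int = 50_000) -> tuple[pd.DataFrame, float]:
    """Windowed genome-landscape table and the LTR-density/CpG correlation.

    Per window: mean level per context (NaN when the window has no passing
    site of that context), gene bp density and LTR bp density. Returns
    (tidy per-window table, Pearson r between LTR density and CpG level over
    windows where CpG level is defined).
    """
    rows = []
    for contig, L in contig_lengths.items():
        n_win = int(np.ceil(L / window))
        sub = levels[levels["contig"] == contig]
        pos = sub["pos"].to_numpy()
        lv = sub["level"].to_numpy()
        ctx = sub["context"].to_numpy()
        win_of = pos // window
        for w in range(n_win):
            s, e = w * window, min((w + 1) * window, L)
            row = {"contig": contig, "window": w, "start": s, "end": e}
            m_w = win_of == w
            for c in CONTEXTS:
                m = m_w & (ctx == c)
                row[f"level_{c}"] = float(lv[m].mean()) if m.any() else np.nan
            for name, spans in (("gene", gene_spans), ("ltr", ltr_spans)):
                bp = sum(max(0, min(e, ge) - max(s, gs))
                         for gs, ge in spans.get(contig, []))
                row[f"{name}_density"] = bp / (e - s)
            rows.append(row)
    df = pd.DataFrame(rows)
    ok = df["level_CpG"].notna()
    if ok.sum() >= 3 and df.loc[ok, "ltr_density"].std() > 0:
        r = float(sstats.pearsonr(df.loc[ok, "ltr_density"],
                                  df.loc[ok, "level_CpG"])[0])
    else:
        r = float("nan")
    return df, r
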
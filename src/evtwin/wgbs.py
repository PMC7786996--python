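"""WGBS twin-discordance analysis.

Per-site bisulfite count tables of two co-twins are filtered (strand
concordance, blacklist intervals, coverage band), intersected on shared
CpGs, and the per-site twin difference |Δβ| is tested for regional
enrichment of large discordance (|Δβ| >= 0.4 by default) with a one-sided
Fisher exact test.  The 0.4 cutoff is not arbitrary: it is the 95% quantile
of the sampling distribution of |Δβ| for two independent 10-read binomial
draws from the same true methylation level — the minimum coverage retained
by the filters — so smaller differences are compatible with read sampling
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import quantile


@dataclass
class WgbsFilters:
    """Site-filter thresholds.

    ``min_coverage`` is exclusive: sites with total reads <= 10 are removed.
    ``high_quantile`` removes putative PCR artifacts above the per-sample
    coverage quantile.  ``delta_threshold`` and ``quantile_level`` define the
    sampling-noise-aware discordance call.
    """

    max_strand_diff: float = 0.20
    min_coverage: int = 10
    high_quantile: float = 0.999
    delta_threshold: float = 0.40
    quantile_level: float = 0.95

    def __post_init__(self):
        for name in ("max_strand_diff", "high_quantile", "delta_threshold", "quantile_level"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass
class EnrichmentRow:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    status: str = "ok"
    haldane: bool = False


def _merge_strands(table: pd.DataFrame, max_strand_diff: float):
    """Strand-concordance check, then collapse strands by summing counts.

    CpGs covered on both strands with |β+ - β-| > ``max_strand_diff`` are
    dropped; single-strand CpGs pass vacuously.
    """
    t = table
    if not (t["pos"].diff().fillna(1) >= 0).all() or not t["chrom"].is_monotonic_increasing:
        t = t.sort_values(["chrom", "pos"], kind="stable")
    grouped = t.groupby(["chrom", "pos"], sort=True)
    agg = grouped.agg(
        count_methylated=("count_methylated", "sum"),
        count_total=("count_total", "sum"),
        n_strands=("strand", "nunique"),
        beta_min=("beta", "min"),
        beta_max=("beta", "max"),
    ).reset_index()
    discordant = (agg["n_strands"] == 2) & (agg["beta_max"] - agg["beta_min"] > max_strand_diff)
    merged = agg.loc[~discordant, ["chrom", "pos", "count_methylated", "count_total"]].copy()
    merged["beta"] = merged["count_methylated"] / merged["count_total"]
    return merged.reset_index(drop=True), int(discordant.sum())


def _in_regions(chrom, pos, regions) -> np.ndarray:
    """Membership of 1-based positions in a per-chromosome sorted, merged
    interval set (1-based inclusive)."""
    mask = np.zeros(len(pos), dtype=bool)
    if regions is None:
        return mask
    intervals = regions.intervals if hasattr(regions, "intervals") else regions
    for c in pd.unique(chrom):
        ivs = intervals.get(c)
        if ivs is None or not len(ivs):
            continue
        starts, ends = np.asarray(ivs)[:, 0], np.asarray(ivs)[:, 1]
        sel = np.asarray(chrom == c)
        p = np.asarray(pos)[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        hit = (idx >= 0) & (p <= ends[np.clip(idx, 0, None)])
        mask[np.where(sel)[0]] = hit
    return mask


def preprocess_wgbs(twin1: pd.DataFrame, twin2: pd.DataFrame, blacklists=None, filters: WgbsFilters | None = None):
    """Filter and pair the per-strand site tables of two co-twins.

    Per sample, in order: (1) strand-concordance check and strand merge;
    (2) blacklist removal; (3) drop coverage <= ``min_coverage``; (4) drop
    coverage above the per-sample ``high_quantile`` (computed after steps
    1-3); (5) keep sites shared by both twins.  Returns the paired table
    (chrom, pos, beta_1, beta_2, abs_diff) and a per-twin removal audit.
    """
    filters = filters or WgbsFilters()
    for name, t in (("twin1", twin1), ("twin2", twin2)):
        if not t.sort_values(["chrom", "pos"], kind="stable")["pos"].equals(
            t["pos"].reset_index(drop=True)
        ) and not t.equals(t.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)):
            raise ValueError(f"{name} table must be sorted by (chrom, pos)")
    audits, merged = {}, {}
    for name, t in (("twin1", twin1), ("twin2", twin2)):
        n_in = t.groupby(["chrom", "pos"]).ngroups
        m, n_strand = _merge_strands(t, filters.max_strand_diff)
        black = _in_regions(m["chrom"], m["pos"], blacklists)
        m = m.loc[~black]
        low = m["count_total"] <= filters.min_coverage
        m = m.loc[~low]
        if len(m):
            hi_cut = quantile(m["count_total"].to_numpy(), filters.high_quantile)
            high = m["count_total"] > hi_cut
        else:
            hi_cut, high = np.nan, pd.Series(False, index=m.index)
        m = m.loc[~high]
        audits[name] = {
            "input_sites": int(n_in),
            "strand_discordant": n_strand,
            "blacklisted": int(black.sum()),
            "low_coverage": int(low.sum()),
            "high_coverage": int(high.sum()),
            "high_coverage_cut": float(hi_cut),
            "output_sites": int(len(m)),
        }
        merged[name] = m
    paired = merged["twin1"].merge(
        merged["twin2"], on=["chrom", "pos"], suffixes=("_1", "_2"), how="inner"
    )
    for name in audits:
        audits[name]["unshared"] = audits[name]["output_sites"] - len(paired)
    paired["abs_diff"] = (paired["beta_1"] - paired["beta_2"]).abs()
    if paired.empty:
        import warnings

        warnings.warn("no sites shared between twins after filtering", stacklevel=2)
    return paired.reset_index(drop=True), audits


def sampling_quantile_threshold(coverage: int, p: float = 0.5, level: float = 0.95) -> float:
    """Smallest q with ``P(|Δβ| <= q) >= level`` under pure read sampling.

    X1, X2 ~ Binomial(coverage, p) independently model two samples of the
    same true methylation level; the distribution of |X1 - X2| / coverage is
    obtained by exact convolution.  At coverage 10 and p = 0.5 (the maximal-
    variance, most conservative choice) the 95% quantile is 0.4.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    pmf = stats.binom.pmf(np.arange(coverage + 1), coverage, p)
    diff = np.convolve(pmf, pmf[::-1])  # support -coverage .. coverage
    folded = diff[coverage:].copy()
    folded[1:] += diff[:coverage][::-1]
    cdf = np.cumsum(folded)
    k = int(np.searchsorted(cdf, level - 1e-12))
    return k / coverage


def region_discordance_enrichment(
    paired: pd.DataFrame, region, delta_threshold: float = 0.40
) -> EnrichmentRow:
    """One-sided Fisher test for enrichment of |Δβ| >= threshold in a region.

    ``region`` is ``(chrom, start, end)`` in 0-based half-open coordinates
    (e.g. the clustered-protocadherin locus chr5:140165876:140892546, hg19).
    Cells: a/b = in-region sites at-or-above / below the threshold, c/d =
    the same outside.  The odds ratio uses a 0.5 Haldane-Anscombe correction
    when any cell is zero (flagged).
    """
    if paired.empty:
        raise ValueError("paired site table is empty")
    chrom, start, end = region
    inside = (
        (paired["chrom"] == chrom)
        & (paired["pos"] > int(start))
        & (paired["pos"] <= int(end))
    ).to_numpy()
    big = (paired["abs_diff"] >= delta_threshold).to_numpy()
    a = int((inside & big).sum())
    b = int((inside & ~big).sum())
    c = int((~inside & big).sum())
    d = int((~inside & ~big).sum())
    if a + b == 0:
        return EnrichmentRow(a, b, c, d, float("nan"), float("nan"), status="no_sites_in_region")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    haldane = 0 in (a, b, c, d)
    if haldane:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    return EnrichmentRow(a, b, c, d, float(orr), float(p), haldane=haldane)
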
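"""Annotation-category, positional, and sequence-composition enrichment.

Targets (e.g. discovered evCpGs) are contrasted against a background (by
default the other variably methylated probes that were tested but not
selected).  Category membership comes from user-supplied annotation schemes
— gene-region groups, chromatin states, imprinted / metastable / mQTL
membership are all just labeled probe sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def _fisher_row(a, b, c, d, alternative):
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    if 0 in (a, b, c, d):
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
        haldane = True
    else:
        orr = a * d / (b * c)
        haldane = False
    return float(orr), float(p), haldane


def category_enrichment(
    target, background, annotation: pd.DataFrame, sided: str = "two", scheme: str | None = None,
    exclude_target_from_background: bool = True,
) -> pd.DataFrame:
    """Fisher exact enrichment of target probes per annotation category.

    ``annotation`` has columns (probe_id, scheme, label); contingency cells
    are a = targets in category, b = targets outside, c = background in,
    d = background outside, with the background excluding the target set by
    default.  ``p_adj`` is Bonferroni over the categories tested.
    """
    target = set(target)
    background = set(background)
    if exclude_target_from_background:
        background = background - target
    if not target or not background:
        raise ValueError("target and background must both be nonempty")
    alt = {"two": "two-sided", "greater": "greater", "less": "less"}[sided]
    ann = annotation if scheme is None else annotation[annotation["scheme"] == scheme]
    rows = []
    cats = sorted(ann["label"].unique())
    for cat in cats:
        members = set(ann.loc[ann["label"] == cat, "probe_id"])
        a = len(target & members)
        b = len(target) - a
        c = len(background & members)
        d = len(background) - c
        orr, p, haldane = _fisher_row(a, b, c, d, alt)
        rows.append(
            {
                "unit": cat, "a": a, "b": b, "c": c, "d": d, "odds_ratio": orr,
                "p": p, "direction": "enriched" if orr >= 1 else "depleted",
                "haldane": haldane,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def _merge_windows(centers: np.ndarray, half: int):
    """Merge overlapping +-half windows around sorted centers."""
    starts = centers - half
    ends = centers + half
    merged = []
    cur_s, cur_e, n = starts[0], ends[0], 1
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e:
            cur_e = max(cur_e, e)
            n += 1
        else:
            merged.append((cur_s, cur_e, n))
            cur_s, cur_e, n = s, e, 1
    merged.append((cur_s, cur_e, n))
    return merged


def positional_enrichment(
    targets: pd.DataFrame, background: pd.DataFrame, window: int = 1000
) -> pd.DataFrame:
    """Unbiased search for loci where targets cluster in the genome.

    A window of ±``window``/2 is placed around every target position;
    overlapping windows are merged, and each merged window gets a one-sided
    Fisher test of target vs background counts inside against outside, with
    Bonferroni over merged windows.  Windows holding >= 2 targets sort
    first.  Inputs are (chrom, pos) tables, positions sorted per chromosome.
    """
    half = window // 2
    n_t, n_b = len(targets), len(background)
    rows = []
    for chrom, tgt in targets.groupby("chrom"):
        pos = np.sort(tgt["pos"].to_numpy())
        bg = np.sort(background.loc[background["chrom"] == chrom, "pos"].to_numpy())
        for s, e, _ in _merge_windows(pos, half):
            a = int(((pos >= s) & (pos <= e)).sum())
            c = int(((bg >= s) & (bg <= e)).sum())
            b, d = n_t - a, n_b - c
            orr, p, haldane = _fisher_row(a, b, c, d, "greater")
            rows.append(
                {
                    "unit": f"{chrom}:{max(s, 0)}-{e}", "chrom": chrom, "start": int(max(s, 0)),
                    "end": int(e), "n_targets": a, "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": orr, "p": p,
                    "direction": "enriched" if orr >= 1 else "depleted", "haldane": haldane,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_adj"] = np.minimum(out["p"] * len(out), 1.0)
    return out.sort_values(
        by=["n_targets", "p"], key=lambda s: -s if s.name == "n_targets" else s
    ).reset_index(drop=True)


def gc_fraction(seq: str) -> float:
    """[G+C] fraction of a sequence over {A,C,G,T,N}; N is ignored in the
    denominator."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    denom = len(s) - s.count("N")
    if denom == 0:
        raise ValueError("sequence has no non-N bases")
    return gc / denom


def gc_content_comparison(target_seqs, background_seqs):
    """Mann-Whitney comparison of per-sequence [G+C] fractions.

    Returns a dict with both fraction vectors, the U statistic, the
    tie-corrected normal-approximation two-sided p value, and the direction
    of the target set relative to background.
    """
    if not len(target_seqs) or not len(background_seqs):
        raise ValueError("both sequence sets must be nonempty")
    x = np.array([gc_fraction(s) for s in target_seqs])
    y = np.array([gc_fraction(s) for s in background_seqs])
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    direction = "diminished" if np.median(x) < np.median(y) else "elevated"
    return {
        "target_gc": x,
        "background_gc": y,
        "u_stat": float(res.statistic),
        "p": float(res.pvalue),
        "direction": direction,
    }
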
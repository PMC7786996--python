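"""Probe-level quality filtering and variability gating.

Before equivalence testing, probes are (i) removed when flagged as noisy in
the manifest (low quality, SNP-containing, cross-reactive, sex chromosomes)
and (ii) gated on inter-individual variability: a probe enters discovery
only if its inter-quartile range (IQR) of beta values exceeds a threshold
chosen to sit above what measurement error alone produces, and — when an
intra-class correlation (ICC) is available — if the ICC shows that technical
variance does not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import iqr as _iqr

#: Fixed precedence used to attribute a multi-flagged probe to one removal
#: category in the audit counts.
FLAG_ORDER = ("low_quality", "snp", "cross_reactive", "chrX", "chrY")


@dataclass
class QcGateParams:
    """Variability-gate thresholds.

    ``iqr_min`` in beta-value units; a beta distribution fitted to mean 0.5
    and sd 0.05 (a measurement-error-only reference) has an IQR of 0.07, so
    probes below that carry no usable inter-individual signal.  ``icc_min``
    follows the published cutoff 0.37 for array probes.
    """

    iqr_min: float = 0.07
    icc_min: float = 0.37
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 <= self.iqr_min <= 1:
            raise ValueError("iqr_min must lie in [0, 1]")
        if not 0 <= self.icc_min <= 1:
            raise ValueError("icc_min must lie in [0, 1]")


def filter_probes(beta: pd.DataFrame, manifest: pd.DataFrame, drop_flags=FLAG_ORDER):
    """Drop probes carrying any of ``drop_flags`` in the manifest.

    Returns ``(filtered_beta, counts)`` where ``counts`` maps each flag to
    the number of probes removed under it.  A probe with several flags is
    counted once, attributed to the first matching flag in :data:`FLAG_ORDER`.
    """
    man = manifest.set_index("probe_id") if "probe_id" in manifest.columns else manifest
    missing = beta.index.difference(man.index)
    if len(missing):
        raise KeyError(f"probes absent from manifest: {sorted(missing)[:10]}")
    flags = man.loc[beta.index, "flags"]
    flag_sets = [
        set() if (isinstance(f, float) and np.isnan(f)) or f in ("", None) else set(str(f).split(","))
        for f in flags
    ]
    drop_flags = [f for f in FLAG_ORDER if f in set(drop_flags)]
    counts = {f: 0 for f in drop_flags}
    keep = np.ones(len(beta), dtype=bool)
    for i, fs in enumerate(flag_sets):
        for f in drop_flags:
            if f in fs:
                counts[f] += 1
                keep[i] = False
                break
    return beta.loc[keep], counts


def _first_replicate_columns(beta: pd.DataFrame, sheet: pd.DataFrame) -> list:
    """One column per individual: the first replicate in sheet order."""
    seen = {}
    for sid, ind in zip(sheet["sample_id"], sheet["individual_id"]):
        if ind not in seen and sid in beta.columns:
            seen[ind] = sid
    return list(seen.values())


def icc_oneway(groups: list) -> float:
    """One-way random-effects ICC(1) from an individuals-as-groups ANOVA.

    ``groups`` is a list of per-individual replicate vectors.  Negative
    estimates are returned as-is.  For unbalanced designs the effective
    group size ``k0 = (N - sum(n_i^2)/N) / (a - 1)`` replaces ``k``.
    """
    sizes = np.array([len(g) for g in groups], dtype=float)
    a, big_n = len(groups), sizes.sum()
    grand = np.concatenate(groups).mean()
    means = np.array([np.mean(g) for g in groups])
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(sum(((np.asarray(g) - m) ** 2).sum() for g, m in zip(groups, means)))
    msb = ssb / (a - 1)
    msw = ssw / (big_n - a)
    k0 = (big_n - (sizes**2).sum() / big_n) / (a - 1)
    if msw == 0:
        return 1.0
    return (msb - msw) / (msb + (k0 - 1) * msw)


def probe_variability(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-probe IQR (one sample per individual) and, when the sheet provides
    technical replicates for at least two individuals, the ICC(1).

    IQR is computed on first-replicate columns only so replicated
    individuals are not double-counted.  Without replicates the ``icc``
    column is NaN and gating falls back to a user-supplied ICC file.
    """
    if beta.shape[1] < 4:
        raise ValueError("need at least 4 samples for variability estimates")
    first_cols = _first_replicate_columns(beta, sheet)
    sub = beta[first_cols].to_numpy()
    q25, q75 = np.quantile(sub, [0.25, 0.75], axis=1)
    out = pd.DataFrame({"probe_id": beta.index, "iqr": q75 - q25}).set_index("probe_id")

    by_ind = {}
    for sid, ind in zip(sheet["sample_id"], sheet["individual_id"]):
        if sid in beta.columns:
            by_ind.setdefault(ind, []).append(sid)
    rep_groups = {ind: cols for ind, cols in by_ind.items() if len(cols) >= 2}
    if len(rep_groups) >= 2:
        col_idx = [[beta.columns.get_loc(c) for c in cols] for cols in rep_groups.values()]
        mat = beta.to_numpy()
        out["icc"] = [icc_oneway([mat[i, idx] for idx in col_idx]) for i in range(len(beta))]
    else:
        out["icc"] = np.nan
    return out.reset_index()


def expected_error_iqr(mean: float, sd: float) -> float:
    """IQR of the beta distribution fitted by method of moments.

    Shape parameters ``a = mean * (mean (1 - mean) / sd^2 - 1)`` and
    ``b = (1 - mean) * (mean (1 - mean) / sd^2 - 1)``; the return value is
    ``q0.75 - q0.25`` of Beta(a, b).  With mean 0.5 and sd 0.05 — a plausible
    measurement-error-only probe — this evaluates to 0.07 (2 dp), the
    default variability-gate cutoff.
    """
    if not 0 < mean < 1:
        raise ValueError("mean must lie in (0, 1)")
    v = sd * sd
    if not 0 < v < mean * (1 - mean):
        raise ValueError("sd^2 must lie in (0, mean*(1-mean)) for a valid beta distribution")
    nu = mean * (1 - mean) / v - 1
    a, b = mean * nu, (1 - mean) * nu
    q25, q75 = stats.beta.ppf([0.25, 0.75], a, b)
    return float(q75 - q25)


def apply_variability_gate(
    variability: pd.DataFrame, params: QcGateParams, icc_file: pd.DataFrame | None = None
) -> pd.Index:
    """Probe ids passing ``iqr >= iqr_min`` and, where ICC is known,
    ``icc >= icc_min``.  ``icc_file`` (columns probe_id, icc) overrides
    replicate-derived ICCs."""
    var = variability.set_index("probe_id")
    icc = var["icc"] if "icc" in var else pd.Series(np.nan, index=var.index)
    if icc_file is not None:
        ext = icc_file.set_index("probe_id")["icc"]
        icc = ext.reindex(var.index).combine_first(icc)
    ok = (var["iqr"] >= params.iqr_min) & (icc.isna() | (icc >= params.icc_min))
    return var.index[ok]


def residualize_covariates(beta: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Remove linear covariate effects probe-wise (batch / cell-composition
    stand-in): OLS of beta on covariates with intercept, output is residual
    plus the probe mean, clamped to [0, 1]."""
    cov = covariates.loc[list(beta.columns)] if not covariates.index.equals(beta.columns) else covariates
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values: {bad}")
    x = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = ["<intercept>"] + list(cov.columns)
        collinear = []
        for j in range(1, x.shape[1]):
            sub = np.delete(x, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")
    b = beta.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(x, b.T, rcond=None)
    resid = b - (x @ coef).T
    out = resid + b.mean(axis=1, keepdims=True)
    return pd.DataFrame(np.clip(out, 0.0, 1.0), index=beta.index, columns=beta.columns)
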
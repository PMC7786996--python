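"""Cross-sectional aging effects: epigenetic clock and epigenetic drift.

A CpG shows *clock* behavior when its mean methylation is linearly
associated with age (OLS of beta on age with sex as covariate) and *drift*
behavior when its inter-individual variance grows with age — detected as
heteroscedasticity of the clock-model residuals with a White-type Lagrange
multiplier test whose auxiliary regression contains age and age², unlike a
plain Breusch-Pagan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class AgingResult:
    probe_id: str
    slope: float
    p_assoc: float
    lm_stat: float
    p_het: float
    cls: str = "neither"


def clock_regression(beta_row, age, sex):
    """OLS ``beta ~ intercept + age + sex``.

    Returns ``(slope, p_assoc, residuals)`` where ``slope`` is the age
    coefficient in beta units per year and ``p_assoc`` its two-sided t-test
    p value.
    """
    y = np.asarray(beta_row, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 samples")
    if np.var(age) == 0:
        raise ValueError("age has zero variance")
    x = sm.add_constant(np.column_stack([age, sex]))
    fit = sm.OLS(y, x).fit()
    return float(fit.params[1]), float(fit.pvalues[1]), np.asarray(fit.resid)


def white_heteroscedasticity_test(residuals, age):
    """LM test of residual variance growing with age.

    Auxiliary OLS of squared residuals on ``1 + age + age²``; the statistic
    is ``n R²`` against chi-square with 2 degrees of freedom.  Constant
    residuals give ``lm_stat = 0`` and ``p_het = 1``.
    """
    e2 = np.asarray(residuals, dtype=float) ** 2
    age = np.asarray(age, dtype=float)
    n = len(e2)
    if n < 10:
        raise ValueError("need at least 10 residuals")
    if np.allclose(e2, e2[0]):
        return 0.0, 1.0
    x = np.column_stack([np.ones(n), age, age**2])
    coef, *_ = np.linalg.lstsq(x, e2, rcond=None)
    fitted = x @ coef
    ss_res = float(((e2 - fitted) ** 2).sum())
    ss_tot = float(((e2 - e2.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    lm = n * max(r2, 0.0)
    return float(lm), float(stats.chi2.sf(lm, df=2))


def evaluate_aging(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Run clock and drift tests for every probe in the matrix."""
    age = sheet.set_index("sample_id").loc[list(beta.columns), "age"].to_numpy(dtype=float)
    sex = sheet.set_index("sample_id").loc[list(beta.columns), "sex"].to_numpy(dtype=float)
    rows = []
    for pid, row in zip(beta.index, beta.to_numpy(dtype=float)):
        slope, p_assoc, resid = clock_regression(row, age, sex)
        lm, p_het = white_heteroscedasticity_test(resid, age)
        rows.append(AgingResult(pid, slope, p_assoc, lm, p_het))
    return pd.DataFrame([vars(r) for r in rows]).rename(columns={"cls": "class"})


def classify_aging(results: pd.DataFrame, alpha: float = 0.05, correction: str = "bonferroni"):
    """Assign clock / drift / both / neither with Bonferroni-corrected calls.

    Returns ``(table, counts)`` where counts include percentages of the
    probe set in each category.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is supported")
    out = results.copy()
    m = len(out)
    thr = alpha / m if m else alpha
    clock = out["p_assoc"] < thr
    drift = out["p_het"] < thr
    out["class"] = np.select(
        [clock & drift, clock, drift], ["both", "clock", "drift"], default="neither"
    )
    counts = {}
    for cls in ("clock", "drift", "both", "neither"):
        k = int((out["class"] == cls).sum())
        counts[cls] = {"n": k, "pct": round(100.0 * k / m, 1) if m else 0.0}
    return out, counts
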
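"""Equivalence-based discovery of stochastically variable CpGs (evCpGs).

For each variably methylated CpG we compare two samples of absolute
methylation differences |Δβ|: one over monozygotic (MZ) twin pairs and one
over unrelated pairs of individuals.  A CpG is "equivalently variable" when
those two samples have statistically equivalent central tendency — tested
with the two one-sided tests (TOST) procedure built on the Yuen trimmed-mean
t test, which tolerates the heavy right tail of |Δβ|.

The equivalence margin ε is not user-guessed: it is calibrated per input
matrix ("normalization branch") as a quantile of the per-CpG trimmed means
of twin |Δβ|, i.e. from the resolution the data itself offers.  Significance
uses a Bonferroni threshold α/m over the m gated CpGs, and the final evCpG
set is the intersection of the per-branch significant sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import quantile
from .preprocess import QcGateParams, apply_variability_gate, probe_variability


@dataclass
class PairDiffs:
    probe_id: str
    twin_diffs: np.ndarray
    unrelated_diffs: np.ndarray


@dataclass
class TostResult:
    probe_id: str
    tm_twin: float
    tm_unrel: float
    delta_hat: float
    se: float
    df: float
    epsilon: float
    p_lower: float
    p_upper: float
    p_equiv: float
    significant: bool = False
    degenerate: bool = False


@dataclass
class DiscoveryConfig:
    """Knobs of the discovery run.

    ``trim`` is the Yuen trimming proportion γ (0.2 is the conventional
    robust default); ``epsilon_quantile`` selects the quantile of per-CpG
    trimmed twin-|Δβ| means used as ε unless ``epsilon`` fixes it directly;
    ``unrelated_mode`` chooses between all cross-family pairs, a random
    subsample of k of them, or a disjoint perfect matching.
    """

    trim: float = 0.2
    epsilon_quantile: float = 0.5
    epsilon: float | None = None
    alpha: float = 0.05
    correction: str = "bonferroni"
    unrelated_mode: str = "all"
    subsample_k: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.trim <= 0.45:
            raise ValueError("trim must lie in [0, 0.45]")
        if self.epsilon is None and not 0 < self.epsilon_quantile < 1:
            raise ValueError("epsilon_quantile must lie in (0, 1)")
        if self.correction != "bonferroni":
            raise ValueError("only Bonferroni correction is supported")
        if self.unrelated_mode not in ("all", "subsample", "disjoint"):
            raise ValueError(f"unknown unrelated_mode: {self.unrelated_mode!r}")
        if self.unrelated_mode == "subsample" and not self.subsample_k:
            raise ValueError("subsample mode requires subsample_k")


# --- pairing ----------------------------------------------------------------


class PairingIndex:
    """Column indices of twin pairs and unrelated pairs for a beta matrix.

    One column per individual enters the pairing (the first technical
    replicate in sheet order); every family must contribute exactly two
    co-twins.
    """

    def __init__(self, beta_columns, sheet: pd.DataFrame):
        first = {}
        fam = {}
        cols = list(beta_columns)
        pos = {c: i for i, c in enumerate(cols)}
        for _, row in sheet.iterrows():
            ind = row["individual_id"]
            if ind not in first and row["sample_id"] in pos:
                first[ind] = pos[row["sample_id"]]
                fam[ind] = row["family_id"]
        fams = {}
        for ind, f in fam.items():
            fams.setdefault(f, []).append(ind)
        bad = {f: len(m) for f, m in fams.items() if len(m) != 2}
        if bad:
            raise ValueError(f"families without exactly 2 members: {bad}")
        self.families = sorted(fams)
        self.twin_a = np.array([first[fams[f][0]] for f in self.families])
        self.twin_b = np.array([first[fams[f][1]] for f in self.families])
        self.individual_cols = np.array(sorted(first.values()))
        self.family_of = np.empty(len(cols), dtype=object)
        for ind, i in first.items():
            self.family_of[i] = fam[ind]
        idx = self.individual_cols
        i, j = np.triu_indices(len(idx), k=1)
        cross = self.family_of[idx[i]] != self.family_of[idx[j]]
        self.unrel_a = idx[i[cross]]
        self.unrel_b = idx[j[cross]]

    @property
    def n_pairs(self) -> int:
        return len(self.families)

    def unrelated_pairs(self, mode: str = "all", k: int | None = None, seed: int | None = None):
        if mode == "all":
            return self.unrel_a, self.unrel_b
        rng = np.random.default_rng(seed)
        if mode == "subsample":
            if k is None or not 1 <= k <= len(self.unrel_a):
                raise ValueError("subsample size k out of range")
            pick = rng.choice(len(self.unrel_a), size=k, replace=False)
            return self.unrel_a[pick], self.unrel_b[pick]
        if mode == "disjoint":
            idx = self.individual_cols.copy()
            for _ in range(1000):
                rng.shuffle(idx)
                a, b = idx[0::2], idx[1::2]
                if (self.family_of[a] != self.family_of[b]).all():
                    return a.copy(), b.copy()
            raise RuntimeError("could not draw a co-twin-free perfect matching")
        raise ValueError(f"unknown unrelated mode: {mode!r}")


def pair_abs_diffs(
    beta_row: pd.Series,
    sheet: pd.DataFrame,
    mode: str = "all",
    k: int | None = None,
    seed: int | None = None,
    pairing: PairingIndex | None = None,
) -> PairDiffs:
    """Absolute beta differences over MZ twin pairs and unrelated pairs."""
    pairing = pairing or PairingIndex(beta_row.index, sheet)
    v = beta_row.to_numpy(dtype=float)
    ua, ub = pairing.unrelated_pairs(mode, k, seed)
    return PairDiffs(
        probe_id=str(beta_row.name),
        twin_diffs=np.abs(v[pairing.twin_a] - v[pairing.twin_b]),
        unrelated_diffs=np.abs(v[ua] - v[ub]),
    )


# --- Yuen trimmed-mean machinery -------------------------------------------


def trimmed_mean(x: np.ndarray, trim: float) -> float:
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    g = int(math.floor(trim * n))
    if n - 2 * g < 2:
        raise ValueError("over-trimmed sample (fewer than 2 values left)")
    return float(x[g : n - g].mean())


def _yuen_components(x: np.ndarray, trim: float):
    """Trimmed mean and the Yuen variance term d = (n-1) s_w^2 / (h (h-1))."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    g = int(math.floor(trim * n))
    h = n - 2 * g
    if h < 2:
        raise ValueError("over-trimmed sample (fewer than 2 values left)")
    tm = float(x[g : n - g].mean())
    w = np.clip(x, x[g], x[n - 1 - g])
    s2w = float(((w - w.mean()) ** 2).sum()) / (n - 1)
    d = (n - 1) * s2w / (h * (h - 1))
    return tm, d, h


def yuen_tost(x, y, epsilon: float, trim: float = 0.2) -> TostResult:
    """TOST equivalence test on γ-trimmed means of two |Δβ| samples.

    Tests H0a: Δ <= -ε and H0b: Δ >= ε where Δ is the difference of trimmed
    means (x minus y); equivalence is declared when both one-sided Yuen
    tests reject, i.e. ``p_equiv = max(p_lower, p_upper)`` is small.  With
    ``trim = 0`` the statistic reduces exactly to the Welch two-sample t.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 5 or len(y) < 5:
        raise ValueError("need at least 5 values per sample")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not 0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    tm1, d1, h1 = _yuen_components(x, trim)
    tm2, d2, h2 = _yuen_components(y, trim)
    delta = tm1 - tm2
    se = math.sqrt(d1 + d2)
    if se == 0.0:
        # both samples constant after winsorization: the decision is exact
        p = 0.0 if abs(delta) < epsilon else 1.0
        warnings.warn("zero Yuen standard error; degenerate TOST decision", stacklevel=2)
        return TostResult(
            probe_id="", tm_twin=tm1, tm_unrel=tm2, delta_hat=delta, se=0.0,
            df=float(h1 + h2 - 2), epsilon=epsilon, p_lower=p, p_upper=p,
            p_equiv=p, degenerate=True,
        )
    df = (d1 + d2) ** 2 / (d1**2 / (h1 - 1) + d2**2 / (h2 - 1))
    p_lower = float(stats.t.sf((delta + epsilon) / se, df))
    p_upper = float(stats.t.cdf((delta - epsilon) / se, df))
    return TostResult(
        probe_id="", tm_twin=tm1, tm_unrel=tm2, delta_hat=delta, se=se, df=df,
        epsilon=epsilon, p_lower=p_lower, p_upper=p_upper,
        p_equiv=max(p_lower, p_upper),
    )


def calibrate_epsilon(trimmed_twin_means, q: float = 0.5) -> float:
    """ε as the q-quantile (linear interpolation) of per-CpG trimmed means
    of twin |Δβ|; fails if the distribution is identically zero."""
    v = np.asarray(trimmed_twin_means, dtype=float)
    if len(v) == 0:
        raise ValueError("no trimmed twin means supplied")
    if not 0 < q < 1:
        raise ValueError("quantile must lie in (0, 1)")
    eps = float(quantile(v, q))
    if eps <= 0:
        raise ValueError("calibrated epsilon is not positive (all-zero twin differences?)")
    return eps


# --- discovery --------------------------------------------------------------


@dataclass
class BranchResult:
    results: pd.DataFrame
    epsilon: float
    m_tested: int
    threshold: float
    tested: pd.Index

    @property
    def significant(self) -> pd.Index:
        return pd.Index(self.results.loc[self.results["significant"], "probe_id"])


@dataclass
class DiscoveryResult:
    branches: list
    evcpgs: pd.Index
    config: DiscoveryConfig
    gate: QcGateParams = field(default_factory=QcGateParams)


def _branch_discovery(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    qc: QcGateParams,
    cfg: DiscoveryConfig,
    icc_file: pd.DataFrame | None,
    pairing: PairingIndex,
) -> BranchResult:
    var = probe_variability(beta, sheet)
    tested = apply_variability_gate(var, qc, icc_file)
    mat = beta.loc[tested]
    ua, ub = pairing.unrelated_pairs(cfg.unrelated_mode, cfg.subsample_k, cfg.seed)

    # pass 1: per-CpG trimmed twin means -> epsilon calibration
    tm_twin = np.empty(len(mat))
    rows = mat.to_numpy(dtype=float)
    for i in range(len(mat)):
        d = np.abs(rows[i, pairing.twin_a] - rows[i, pairing.twin_b])
        tm_twin[i] = trimmed_mean(d, cfg.trim)
    epsilon = cfg.epsilon if cfg.epsilon is not None else calibrate_epsilon(tm_twin, cfg.epsilon_quantile)

    m = len(mat)
    threshold = cfg.alpha / m if m else cfg.alpha
    # pass 2: streamed Yuen-TOST, one probe's diff vectors at a time
    out = []
    for i, pid in enumerate(mat.index):
        v = rows[i]
        res = yuen_tost(
            np.abs(v[pairing.twin_a] - v[pairing.twin_b]),
            np.abs(v[ua] - v[ub]),
            epsilon=epsilon,
            trim=cfg.trim,
        )
        res.probe_id = pid
        res.significant = res.p_equiv < threshold
        out.append(res)
    results = pd.DataFrame([vars(r) for r in out])
    return BranchResult(results=results, epsilon=epsilon, m_tested=m, threshold=threshold, tested=tested)


def discover_evcpgs(
    branches,
    sheet: pd.DataFrame,
    manifest: pd.DataFrame | None = None,
    qc: QcGateParams | None = None,
    cfg: DiscoveryConfig | None = None,
    icc_file: pd.DataFrame | None = None,
) -> DiscoveryResult:
    """Run the full discovery on one or more normalization branches.

    Per branch: manifest flag filtering (when a manifest is given) →
    variability gate → ε calibration → per-CpG Yuen-TOST → Bonferroni at
    α/m.  The returned evCpG set is the intersection of per-branch
    significant sets.
    """
    from .preprocess import filter_probes

    if isinstance(branches, pd.DataFrame):
        branches = [branches]
    if not branches:
        raise ValueError("need at least one normalization branch")
    base_index = branches[0].index
    for b in branches[1:]:
        if not b.index.equals(base_index) or not list(b.columns) == list(branches[0].columns):
            raise ValueError("branches must share probe ids and samples")
    qc = qc or QcGateParams()
    cfg = cfg or DiscoveryConfig()
    pairing = PairingIndex(branches[0].columns, sheet)

    branch_results = []
    for b in branches:
        if manifest is not None:
            b, _ = filter_probes(b, manifest)
        branch_results.append(_branch_discovery(b, sheet, qc, cfg, icc_file, pairing))
    evcpgs = branch_results[0].significant
    for br in branch_results[1:]:
        evcpgs = evcpgs.intersection(br.significant)
    return DiscoveryResult(branches=branch_results, evcpgs=evcpgs, config=cfg, gate=qc)


# --- summaries and verification --------------------------------------------


def twin_concordance(beta: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-probe agreement between co-twins vs total methylation range.

    Concordance is Lin's concordance correlation coefficient on the
    order-symmetrized twin pairing (each pair contributes both (a, b) and
    (b, a)); range is q0.975 - q0.025 of all betas at the probe.  Probes with
    zero variance get concordance 0 and a flag.
    """
    pairing = PairingIndex(beta.columns, sheet)
    mat = beta.to_numpy(dtype=float)
    a = mat[:, pairing.twin_a]
    b = mat[:, pairing.twin_b]
    x = np.concatenate([a, b], axis=1)
    y = np.concatenate([b, a], axis=1)
    mx = x.mean(axis=1)
    vx = x.var(axis=1)
    cov = ((x - mx[:, None]) * (y - mx[:, None])).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ccc = np.where(vx > 0, cov / vx, 0.0)  # symmetrized means/vars are equal
    q_lo, q_hi = np.quantile(mat, [0.025, 0.975], axis=1)
    return pd.DataFrame(
        {
            "probe_id": beta.index,
            "concordance": ccc,
            "range": q_hi - q_lo,
            "zero_variance": vx == 0,
        }
    )


def independence_check(
    branch: pd.DataFrame,
    sheet: pd.DataFrame,
    cfg: DiscoveryConfig | None = None,
    n_resamples: int = 25,
    seed: int = 0,
    qc: QcGateParams | None = None,
):
    """Verify that exhausting all unrelated pairs does not distort decisions.

    The all-pairs |Δβ| sample reuses every individual many times, so its
    values are dependent.  As a guard, discovery is repeated with
    ``unrelated_mode='disjoint'`` — random perfect matchings in which each
    individual occurs in exactly one unrelated pair — and per-CpG decisions
    are compared against the all-pairs run.  Note the disjoint runs rest on
    n_pairs unrelated differences instead of ~2 n_pairs^2, so their
    per-run power is intrinsically lower.

    Returns ``(table, summary)``: per-CpG agreement fractions and overall /
    evCpG-restricted agreement rates plus the majority-vote agreement.
    """
    cfg = cfg or DiscoveryConfig()
    pairing = PairingIndex(branch.columns, sheet)
    if pairing.n_pairs < 10:
        raise ValueError("need at least 10 twin pairs for disjoint matchings")
    full = discover_evcpgs([branch], sheet, cfg=cfg, qc=qc)
    ref = full.branches[0].results.set_index("probe_id")["significant"]
    agree = np.zeros(len(ref))
    flagged = np.zeros(len(ref))
    for r in range(n_resamples):
        cfg_r = replace(cfg, unrelated_mode="disjoint", seed=seed + r)
        run = discover_evcpgs([branch], sheet, cfg=cfg_r, qc=qc)
        dec = run.branches[0].results.set_index("probe_id")["significant"].reindex(ref.index)
        agree += (dec == ref).to_numpy()
        flagged += dec.to_numpy()
    table = pd.DataFrame(
        {
            "probe_id": ref.index,
            "all_pairs_significant": ref.to_numpy(),
            "agreement": agree / n_resamples,
            "resample_flag_rate": flagged / n_resamples,
        }
    )
    is_ev = table["all_pairs_significant"].to_numpy()
    majority = ((table["resample_flag_rate"] > 0.5) == is_ev).mean()
    summary = {
        "n_resamples": n_resamples,
        "n_tested": int(len(table)),
        "n_evcpgs_all_pairs": int(is_ev.sum()),
        "overall_agreement": float(table["agreement"].mean()),
        "evcpg_agreement": float(table.loc[is_ev, "agreement"].mean()) if is_ev.any() else float("nan"),
        "majority_vote_agreement": float(majority),
    }
    return table, summary
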
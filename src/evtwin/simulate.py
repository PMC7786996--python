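"""Synthetic twin cohorts with known stochastic / genetic / noise structure.

The generators produce the data shapes the discovery pipeline consumes:
array-style beta matrices for monozygotic (MZ) twin cohorts, technical and
longitudinal replicates, cross-sectional aging cohorts, and per-site
read-count tables for a whole-genome bisulfite sequencing (WGBS) twin pair.

Generative model for the array cohort
-------------------------------------
Every probe carries a true methylation level per individual; observed values
are produced by adding Normal measurement noise on the log-odds (logit)
scale and mapping back through the inverse logit, which keeps betas inside
(0, 1) without clipping artifacts and makes variance components analytic on
the logit scale.  Four probe classes are simulated:

``error_only``
    one shared true beta; all observed spread is measurement error.
``genetic``
    a family-level genotype ``g ~ Binomial(2, maf)`` (Hardy-Weinberg, shared
    by co-twins) shifts the true beta by ``g * effect``; an mQTL stand-in.
``stochastic``
    each individual draws an independent true logit around the baseline;
    co-twins are as different as unrelated individuals.  This is the
    equivalently-variable (evCpG) truth class.
``mixed``
    genotype shift plus per-individual stochastic noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import clamp_beta, inv_logit, logit

CLASS_ORDER = ("error_only", "genetic", "stochastic", "mixed")

# Baseline (true mean beta) sampling ranges per probe class.  Stochastic
# epialleles sit at intermediate methylation, where inter-individual drift
# is visible on the beta scale; genetic baselines leave headroom for up to
# two effect-allele shifts.
BASELINE_RANGES = {
    "error_only": (0.10, 0.90),
    "genetic": (0.10, 0.45),
    "stochastic": (0.40, 0.60),
    "mixed": (0.30, 0.60),
}


@dataclass
class CohortConfig:
    """Parameters of the simulated MZ twin array cohort.

    ``sigma_meas`` and ``sigma_stoch`` are standard deviations on the logit
    scale (dimensionless); ``effect_range`` is a per-allele shift interval in
    beta units; ``batch_shift`` is a per-batch logit offset.
    """

    n_pairs: int = 200
    n_cpgs: int = 5000
    class_fractions: dict = field(
        default_factory=lambda: {
            "error_only": 0.70,
            "genetic": 0.20,
            "stochastic": 0.05,
            "mixed": 0.05,
        }
    )
    sigma_meas: float = 0.12
    sigma_stoch: float = 0.22
    maf_range: tuple = (0.05, 0.50)
    effect_range: tuple = (0.05, 0.30)
    batch_shift: float = 0.0
    n_batches: int = 1
    seed: int = 1

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2 (unrelated pairs undefined otherwise)")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        if set(self.class_fractions) - set(CLASS_ORDER):
            raise ValueError(f"unknown probe classes: {set(self.class_fractions) - set(CLASS_ORDER)}")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1 (got {total})")
        if min(self.class_fractions.values()) < 0:
            raise ValueError("class_fractions must be non-negative")
        for name in ("sigma_meas", "sigma_stoch", "batch_shift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        lo, hi = self.effect_range
        if not (0 <= lo <= hi <= 0.3):
            raise ValueError("effect_range must lie in [0, 0.3]")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class TwinCohort:
    """A simulated cohort: observed betas, sample sheet, and ground truth.

    ``true_logit`` (probes x individuals, logit scale) is retained so that
    replicate simulations can re-observe the same underlying state.
    """

    beta: pd.DataFrame
    sheet: pd.DataFrame
    truth: pd.DataFrame
    true_logit: pd.DataFrame
    config: CohortConfig
    genotype: pd.DataFrame | None = None  # genetic/mixed probes x individuals

    def __iter__(self):  # allow (beta, sheet, truth) unpacking
        return iter((self.beta, self.sheet, self.truth))


def _class_counts(fractions: dict, n_cpgs: int) -> dict:
    """Largest-remainder apportionment of probes to classes."""
    raw = {c: fractions.get(c, 0.0) * n_cpgs for c in CLASS_ORDER}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n_cpgs - sum(counts.values())
    for c in sorted(CLASS_ORDER, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    return counts


def _batch_effects(rng, n_probes: int, n_batches: int, batch_shift: float):
    """Probe-specific chip effects: one logit offset per (probe, batch),
    drawn N(0, batch_shift) with the first batch as reference.  Array batch
    effects vary in sign and size across probes; ``batch_shift`` sets their
    scale."""
    eff = np.zeros((n_probes, n_batches))
    if n_batches > 1 and batch_shift > 0:
        eff[:, 1:] = rng.normal(0.0, batch_shift, size=(n_probes, n_batches - 1))
    return eff


def simulate_twin_cohort(config: CohortConfig) -> TwinCohort:
    """Simulate an MZ twin cohort of ``2 * n_pairs`` individuals.

    Returns a :class:`TwinCohort`; unpacking yields ``(beta, sheet, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    n_ind = 2 * config.n_pairs
    counts = _class_counts(config.class_fractions, config.n_cpgs)

    families = [f"F{i + 1:04d}" for i in range(config.n_pairs)]
    individuals = [f"{fam}_T{t}" for fam in families for t in (1, 2)]
    fam_of = np.repeat(np.arange(config.n_pairs), 2)

    probe_ids, classes, baselines, effects, mafs = [], [], [], [], []
    geno_rows, geno_ids = [], []
    true_logit = np.empty((config.n_cpgs, n_ind))
    row = 0
    for cls in CLASS_ORDER:
        k = counts[cls]
        if k == 0:
            continue
        lo, hi = BASELINE_RANGES[cls]
        base = rng.uniform(lo, hi, size=k)
        eff = np.zeros(k)
        maf = np.full(k, np.nan)
        if cls in ("genetic", "mixed"):
            eff = rng.uniform(*config.effect_range, size=k)
            maf = rng.uniform(*config.maf_range, size=k)
            geno = rng.binomial(2, maf[:, None], size=(k, config.n_pairs))
            geno_rows.append(geno[:, fam_of])
            geno_ids += [f"cg{j + 1:07d}" for j in range(row, row + k)]
            true_beta = clamp_beta(base[:, None] + geno[:, fam_of] * eff[:, None])
            tl = logit(true_beta)
            if cls == "mixed":
                tl = tl + rng.normal(0.0, config.sigma_stoch, size=(k, n_ind))
        elif cls == "stochastic":
            tl = logit(base)[:, None] + rng.normal(
                0.0, config.sigma_stoch, size=(k, n_ind)
            )
        else:  # error_only: one true value shared by everyone
            tl = np.broadcast_to(logit(base)[:, None], (k, n_ind)).copy()
        true_logit[row : row + k] = tl
        probe_ids += [f"cg{j + 1:07d}" for j in range(row, row + k)]
        classes += [cls] * k
        baselines.append(base)
        effects.append(eff)
        mafs.append(maf)
        row += k

    batch = np.arange(n_ind) % config.n_batches
    chip = _batch_effects(rng, config.n_cpgs, config.n_batches, config.batch_shift)
    observed = inv_logit(
        true_logit
        + rng.normal(0.0, config.sigma_meas, size=true_logit.shape)
        + chip[:, batch]
    )

    beta = pd.DataFrame(observed, index=pd.Index(probe_ids, name="probe_id"), columns=individuals)
    sheet = pd.DataFrame(
        {
            "sample_id": individuals,
            "individual_id": individuals,
            "family_id": [families[f] for f in fam_of],
            "role": ["T1", "T2"] * config.n_pairs,
            "replicate_id": 1,
            "batch": [f"batch{b}" for b in batch],
            "tissue": "blood",
        }
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "class": classes,
            "baseline": np.concatenate(baselines),
            "effect": np.concatenate(effects),
            "maf": np.concatenate(mafs),
        }
    )
    genotype = (
        pd.DataFrame(np.vstack(geno_rows), index=pd.Index(geno_ids, name="probe_id"), columns=individuals)
        if geno_rows
        else None
    )
    return TwinCohort(
        beta, sheet, truth,
        pd.DataFrame(true_logit, index=beta.index, columns=individuals),
        config, genotype,
    )


def simulate_replicates(
    cohort: TwinCohort,
    mode: str,
    k: int = 2,
    sigma_time: float = 0.0,
    seed: int = 0,
    n_batches: int | None = None,
    batch_shift: float | None = None,
):
    """Re-observe a cohort ``k`` times as technical or longitudinal replicates.

    Technical replicates re-measure the same true state with fresh noise;
    each replication round is processed on its own chip batch (logit offset
    ``batch_shift * round``).  Longitudinal replicates let the true logit
    perform a random walk with step standard deviation ``sigma_time``.

    Returns ``(beta, sheet)`` with ``replicate_id`` / ``timepoint`` columns.
    """
    if mode not in ("technical", "longitudinal"):
        raise ValueError(f"unknown replicate mode: {mode!r}")
    if k < 2:
        raise ValueError("k must be >= 2")
    cfg = cohort.config
    n_batches = cfg.n_batches if n_batches is None else n_batches
    batch_shift = cfg.batch_shift if batch_shift is None else batch_shift
    rng = np.random.default_rng(seed)

    tl = cohort.true_logit.to_numpy()
    chip = _batch_effects(rng, len(tl), n_batches, batch_shift)
    cols, frames, rows = [], [], []
    for r in range(k):
        if mode == "longitudinal" and r > 0 and sigma_time > 0:
            tl = tl + rng.normal(0.0, sigma_time, size=tl.shape)
        offset = chip[:, [r % n_batches]] if mode == "technical" else 0.0
        noise = rng.normal(0.0, cfg.sigma_meas, size=tl.shape) if cfg.sigma_meas > 0 else 0.0
        frames.append(inv_logit(tl + noise + offset))
        for ind, fam in zip(cohort.sheet["individual_id"], cohort.sheet["family_id"]):
            cols.append(f"{ind}_r{r + 1}")
            rows.append(
                {
                    "sample_id": f"{ind}_r{r + 1}",
                    "individual_id": ind,
                    "family_id": fam,
                    "replicate_id": r + 1,
                    "timepoint": r + 1 if mode == "longitudinal" else 1,
                    "batch": f"chip{r % n_batches}" if mode == "technical" else "batch0",
                    "tissue": "blood",
                }
            )
    beta = pd.DataFrame(
        np.hstack(frames), index=cohort.beta.index, columns=cols
    )
    sheet = pd.DataFrame(rows)
    # order columns sample-major (all replicates of one individual adjacent)
    order = sorted(range(len(cols)), key=lambda i: (rows[i]["individual_id"], rows[i]["replicate_id"]))
    beta = beta.iloc[:, order]
    sheet = sheet.iloc[order].reset_index(drop=True)
    return beta, sheet


def simulate_aging_cohort(
    n: int,
    age_range: tuple = (14.0, 94.0),
    n_cpgs: dict | None = None,
    slope: float = 0.006,
    rate: float = 0.015,
    sigma0: float = 0.25,
    sex_effect: float = 0.0,
    seed: int = 0,
):
    """Cross-sectional cohort with epigenetic clock and drift CpGs.

    ``clock`` probes shift their mean logit by ``slope`` per year; ``drift``
    probes grow their logit standard deviation by ``rate * sigma0`` per year
    starting from ``sigma0`` at the youngest age; ``both`` probes do both;
    ``neither`` probes are age-invariant.  Ages are uniform over
    ``age_range``; sex is Bernoulli(0.5) and shifts the mean logit by
    ``sex_effect``.

    Returns ``(beta, sheet, truth)``.
    """
    if n < 30:
        raise ValueError("n must be >= 30")
    lo, hi = age_range
    if not hi > lo:
        raise ValueError("age_range must have positive width")
    n_cpgs = dict(n_cpgs or {"clock": 100, "drift": 100, "neither": 300})
    known = {"clock", "drift", "both", "neither"}
    if set(n_cpgs) - known:
        raise ValueError(f"unknown aging classes: {set(n_cpgs) - known}")

    rng = np.random.default_rng(seed)
    age = rng.uniform(lo, hi, size=n)
    sex = rng.integers(0, 2, size=n)

    probe_ids, classes, baselines, eff = [], [], [], []
    blocks = []
    start = 0
    for cls in ("clock", "drift", "both", "neither"):
        k = n_cpgs.get(cls, 0)
        if k == 0:
            continue
        base = rng.uniform(0.3, 0.7, size=k)
        mu = logit(base)[:, None] + sex_effect * sex[None, :]
        if cls in ("clock", "both"):
            mu = mu + slope * (age - lo)[None, :]
        sd = np.full((k, n), sigma0)
        if cls in ("drift", "both"):
            sd = sigma0 * (1.0 + rate * (age - lo))[None, :] * np.ones((k, 1))
        blocks.append(inv_logit(mu + rng.normal(0.0, 1.0, size=(k, n)) * sd))
        probe_ids += [f"cg{j + 1:07d}" for j in range(start, start + k)]
        classes += [cls] * k
        baselines.append(base)
        eff += [slope if cls in ("clock", "both") else (rate if cls == "drift" else 0.0)] * k
        start += k

    samples = [f"S{i + 1:04d}" for i in range(n)]
    beta = pd.DataFrame(np.vstack(blocks), index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "individual_id": samples,
            "family_id": samples,
            "age": age,
            "sex": sex,
        }
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "class": classes,
            "baseline": np.concatenate(baselines),
            "effect": eff,
            "maf": np.nan,
        }
    )
    return beta, sheet, truth


# --- WGBS twin pair ---------------------------------------------------------

# Bimodal true-methylation mixture for CpG sites: most of the genome is
# either solidly methylated or unmethylated, which also keeps binomial
# sampling noise from mimicking strand discordance at moderate coverage.
_BETA_SHAPE_LOW = (0.6, 80.0)
_BETA_SHAPE_HIGH = (80.0, 0.6)


@dataclass
class WgbsSimConfig:
    """Parameters of the simulated WGBS twin pair (one toy chromosome)."""

    n_sites: int = 20000
    chrom: str = "chrS"
    chrom_length: int = 2_000_000
    mean_coverage: float = 30.0
    coverage_dispersion: float = 5.0
    region: tuple = (1_500_000, 1_700_000)
    frac_discordant_in_region: float = 0.3
    frac_blacklist: float = 0.01
    frac_strand_artifact: float = 0.01
    seed: int = 1

    def __post_init__(self):
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")
        for name in ("frac_discordant_in_region", "frac_blacklist", "frac_strand_artifact"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        s, e = self.region
        if not (0 <= s < e <= self.chrom_length):
            raise ValueError("region must lie within [0, chrom_length)")
        if self.n_sites < 1 or self.n_sites > self.chrom_length:
            raise ValueError("n_sites must be in [1, chrom_length]")


@dataclass
class WgbsPair:
    """Simulated per-strand site tables for two co-twins plus ground truth."""

    twin1: pd.DataFrame
    twin2: pd.DataFrame
    truth: pd.DataFrame
    blacklist: pd.DataFrame  # BED-style: chrom, start (0-based), end

    def __iter__(self):
        return iter((self.twin1, self.twin2, self.truth))


def _observe_twin(rng, chrom, pos, true_beta, artifact, cfg) -> pd.DataFrame:
    n = len(pos)
    r = cfg.coverage_dispersion
    total = rng.negative_binomial(r, r / (r + cfg.mean_coverage), size=n)
    plus = rng.binomial(total, 0.5)
    minus = total - plus
    beta_minus = true_beta.copy()
    # forced strand artifact: minus-strand truth displaced by 0.7
    beta_minus[artifact] = np.where(
        true_beta[artifact] <= 0.3, true_beta[artifact] + 0.7, true_beta[artifact] - 0.7
    )
    meth_plus = rng.binomial(plus, true_beta)
    meth_minus = rng.binomial(minus, beta_minus)
    rows = []
    for strand, cov, meth in (("+", plus, meth_plus), ("-", minus, meth_minus)):
        keep = cov > 0
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos[keep],
                    "strand": strand,
                    "count_methylated": meth[keep],
                    "count_total": cov[keep],
                    "beta": meth[keep] / cov[keep],
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def simulate_wgbs_pair(config: WgbsSimConfig) -> WgbsPair:
    """Simulate per-strand WGBS count tables for an MZ twin pair.

    Outside ``region`` co-twins share the true methylation level; inside it a
    fraction ``frac_discordant_in_region`` of sites get twin-specific truths
    at least 0.5 apart (the discordance-enriched locus).  Coverage is
    negative binomial, reads are split binomially across strands, and a
    fraction of sites per twin carry a forced strand artifact.
    """
    rng = np.random.default_rng(config.seed)
    pos = np.sort(rng.choice(config.chrom_length, size=config.n_sites, replace=False)) + 1

    comp = rng.random(config.n_sites) < 0.5
    base = np.where(
        comp,
        rng.beta(*_BETA_SHAPE_LOW, size=config.n_sites),
        rng.beta(*_BETA_SHAPE_HIGH, size=config.n_sites),
    )
    s, e = config.region
    in_region = (pos > s) & (pos <= e)  # region given 0-based half-open
    discordant = in_region & (rng.random(config.n_sites) < config.frac_discordant_in_region)
    low = rng.uniform(0.03, 0.20, size=config.n_sites)
    high = rng.uniform(0.80, 0.97, size=config.n_sites)
    flip = rng.random(config.n_sites) < 0.5
    beta1 = np.where(discordant, np.where(flip, low, high), base)
    beta2 = np.where(discordant, np.where(flip, high, low), base)

    art1 = rng.random(config.n_sites) < config.frac_strand_artifact
    art2 = rng.random(config.n_sites) < config.frac_strand_artifact
    blacklisted = rng.random(config.n_sites) < config.frac_blacklist

    twin1 = _observe_twin(rng, config.chrom, pos, beta1, art1, config)
    twin2 = _observe_twin(rng, config.chrom, pos, beta2, art2, config)
    truth = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": pos,
            "in_region": in_region,
            "discordant": discordant,
            "blacklisted": blacklisted,
            "strand_artifact_twin1": art1,
            "strand_artifact_twin2": art2,
        }
    )
    bl = pd.DataFrame(
        {"chrom": config.chrom, "start": pos[blacklisted] - 1, "end": pos[blacklisted]}
    )
    return WgbsPair(twin1, twin2, truth, bl)
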
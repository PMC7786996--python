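# Methods

## Scope and data model

The pipeline consumes already-normalized beta-value matrices (probes ×
samples, values in [0, 1]); raw-array processing (IDAT reading,
normalization, ComBat, cell-type deconvolution) is out of scope.  Several
normalized matrices may be supplied as parallel "branches"; discovery is
run per branch and the final evCpG set is the intersection of the
per-branch significant sets, which guards against normalization-specific
artifacts.  Batch and cell-composition corrections are represented by a
generic covariate residualization (`residualize_covariates`): per-probe OLS
on user-supplied covariates, residual plus probe mean, clamped to [0, 1].

Coordinates are 1-based inclusive internally; BED inputs (0-based
half-open) are converted once at read time.  Quantiles are linearly
interpolated ("type 7") everywhere: the IQR gate, coverage cuts and ε
calibration.

## Probe gating

A probe enters equivalence testing only if it shows usable inter-individual
variation:

* **IQR ≥ 0.07** (beta units), computed over one sample per individual
  (first technical replicate in sheet order, to avoid double-counting
  replicated individuals).  The cutoff is the IQR of a beta distribution
  fitted by method of moments to mean 0.5 and sd 0.05, i.e. the spread a
  pure measurement-error probe of typical intermediate methylation would
  show.  The exact value is 0.0679; 0.07 at the 2-dp precision used for
  the gate.
* **ICC ≥ 0.37** where an intra-class correlation is available — either
  computed from technical replicates as the one-way random-effects ICC(1),
  `(MSB − MSW)/(MSB + (k−1)·MSW)` with the unbalanced-design effective
  group size k₀, or supplied as an external per-probe file.  Negative
  ICC(1) estimates are reported as-is.  Probes without ICC information are
  gated on IQR alone.

Manifest-flagged probes (low quality, SNP-containing, cross-reactive,
X/Y-chromosomal) are removed first; a multi-flagged probe is counted once
under the first flag in that fixed order.

## Equivalence testing

For a gated CpG with per-sample betas, twin differences are taken over the
n families and unrelated differences over all cross-family individual
pairs (~2n² values; both co-twins participate).  The Yuen statistic uses
γ-trimmed means (γ = 0.2; g = ⌊γn⌋ values trimmed per tail, h = n − 2g
retained) and winsorized variances, with the Welch–Satterthwaite df; at
γ = 0 it reduces exactly to the Welch two-sample t, which the tests verify
to 1e-10.  The TOST p value is the larger of the two one-sided p values;
equivalence requires it to fall below the Bonferroni threshold α/m, m being
the number of gated CpGs in the branch.

**ε calibration.**  ε is the median (configurable quantile) of the per-CpG
trimmed means of twin |Δβ| across all gated CpGs, computed per branch.
Since most gated CpGs are genetically driven — whose co-twins differ only
by measurement noise — ε lands at the resolution the assay itself offers
(≈ 0.028 beta units on the reference synthetic cohort), which is the
largest margin that still rejects mQTL-like CpGs whose unrelated-vs-twin
trimmed-mean gap starts around 0.030 at per-allele effect 0.1 and MAF 0.2.

**Known approximations.**  The unrelated |Δβ| sample reuses each individual
~2n times, so its values are dependent, and the test treats the two
samples as independent.  `independence_check` guards this: discovery is
re-run on random *disjoint* perfect matchings (each individual in exactly
one unrelated pair, never with its co-twin) and decisions are compared.
On the reference cohort the overall decision agreement across 25 rematches
is 0.93 and majority-vote recovery of the evCpG set is 0.95.  Single
disjoint runs rest on n instead of ~2n² unrelated differences — a √2
larger standard error — so their per-run re-flagging of individual evCpGs
is intrinsically noisier (~0.69); the function reports all three rates.

**Degenerate cases.**  Zero Yuen SE with |Δ̂| inside (−ε, ε) yields
p_equiv = 0 (flagged and warned); outside, p_equiv = 1.

`twin_concordance` summarizes effect sizes as Lin's concordance
correlation coefficient on the order-symmetrized twin pairing against the
2.5–97.5% methylation range; zero-variance probes are flagged with
concordance 0.  The symmetrized CCC is one reasonable agreement summary
among several; it is exactly 1 for identical co-twins and ~0 for
independent ones.

## Aging: clock and drift

Per CpG, OLS `beta ~ intercept + age + sex` gives the clock slope and its
two-sided t-test p value.  Drift (variance growth with age) is tested on
the residuals with a White-type LM statistic whose auxiliary regression is
squared residuals on {1, age, age²} — the quadratic term distinguishes it
from a plain Breusch–Pagan — with n·R² against χ²(2).  Sex enters the mean
model only.  Classification at Bonferroni-corrected α = 0.05: both /
clock / drift / neither.  Constant residuals give LM = 0, p = 1.

## Cluster evaluation

Sample columns are clustered agglomeratively (Euclidean distance, average
linkage by default) and cut at k = number of truth groups; scores are the
adjusted Rand index and cluster purity against individual, twin-pair,
batch or timepoint labels.  Negative controls are the top-ranked mQTL
probes (rank 1 = most significant; ties broken by probe id).  Classical
(Torgerson) MDS embeds samples for tissue comparisons; axes are signed so
the first nonzero loading is positive.

## WGBS twin discordance

Per co-twin sample, in order: (1) CpGs covered on both strands with
strand-wise beta difference > 0.20 are dropped, otherwise strand counts
are summed (single-strand CpGs pass vacuously); (2) sites in blacklist
intervals are dropped; (3) sites with total coverage ≤ 10 reads are
dropped; (4) sites above the per-sample 99.9% coverage quantile (computed
after steps 1–3; the order affects the cut and is recorded in the audit)
are dropped as PCR-artifact suspects.  Only sites present in both twins
are kept, and every step's removal count is audited (input = output + Σ
removals).

Twin differences ≥ 0.4 are called discordant: 0.4 is the 95% quantile of
|Δβ| between two independent Binomial(c, p)/c draws at the minimum
retained coverage c = 11 → computed conservatively at c = 10 and p = 0.5
(maximal binomial variance; the threshold is symmetric in p ↔ 1−p).  The
exact distribution comes from convolving the binomial pmf with itself;
the returned threshold is the smallest lattice point q = k/c with
P(|Δβ| ≤ q) ≥ level.  Because of the lattice, the threshold is
non-increasing in coverage only up to one grid step.

Regional enrichment (e.g. the clustered-protocadherin locus
chr5:140165876-140892546, hg19) uses a one-sided (greater) Fisher exact
test on in-region vs out-of-region sites at/above vs below the threshold;
odds ratios use a 0.5 Haldane–Anscombe correction when a cell is zero.  A
region with no covered sites returns an explicit not-computable status.

## Annotation enrichment

Category enrichment is a Fisher exact test per annotation label with the
background excluding the target set by default (targets are contrasted
against the tested-but-not-selected probes), Bonferroni over labels.
Positional enrichment places ±500 bp windows around targets, merges
overlaps, and tests each merged window one-sided with Bonferroni over
windows; windows holding ≥ 2 targets sort first.  [G+C] content uses the
tie-corrected normal-approximation Mann–Whitney test on per-sequence
fractions (N bases excluded from the denominator); sequences are supplied
as FASTA windows around the probes.

## The synthetic-cohort generator

Observed betas are generated as
`inverse-logit(logit(true) + N(0, σ_meas) + chip effect)`; true betas are
clamped to [0.001, 0.999] before logit.  Logit-normal noise keeps values
in (0, 1) without clipping and makes variance components analytic on the
logit scale.  Probe classes:

| class | true value model | default fraction |
|---|---|---|
| error_only | one shared beta, baseline U(0.10, 0.90) | 0.70 |
| genetic | family genotype g ~ Binomial(2, maf), beta = clamp(baseline + g·effect); baseline U(0.10, 0.45), effect U(0.05, 0.30), MAF U(0.05, 0.50) | 0.20 |
| stochastic | per-individual logit ~ N(logit(baseline), σ_stoch), co-twins independent; baseline U(0.40, 0.60) | 0.05 |
| mixed | genotype shift plus per-individual logit noise | 0.05 |

Defaults: 200 twin pairs, 5000 CpGs, σ_meas = 0.12, σ_stoch = 0.22,
seed 1.  The magnitudes were fixed once, from a design calculation rather
than any external dataset: σ_meas = 0.12 puts the beta-scale measurement sd
at ≈ 0.03 for an intermediate-methylation probe (matching the beta-IQR
reference above, so error-only probes sit safely below the 0.07 gate), and
σ_stoch = 0.22 with intermediate baselines — where metastable,
stochastically set loci live — puts stochastic probes' IQR at 0.08–0.09
(safely above the gate) and their trimmed twin means ≈ 0.06, well separated
from both the calibrated ε and the genetic rejection region.  Genotypes are
family-level, Hardy–Weinberg at the drawn MAF, and retained in the output
for parameter-recovery checks.

Chip (batch) effects are probe-specific: one logit offset per (probe,
batch) drawn N(0, batch_shift), the first batch as reference.  A constant
per-batch shift cannot reproduce the observed dominance of chip structure
over genotype structure in negative-control probes, because it cancels in
probe-wise contrasts; probe-specific effects are also what array batch
artifacts look like.  Technical replicates re-observe the same true values
with fresh noise, each replication round on its own chip; longitudinal
replicates let the true logit random-walk with step sd σ_time.

The aging generator shifts the mean logit by `slope` per year (clock),
grows the logit sd linearly as `σ0·(1 + rate·(age − age_min))` (drift), or
both.  Defaults slope = 0.006/yr, rate = 0.015/yr, σ0 = 0.25 keep the four
truth classes cleanly recoverable at cohort scale; substantially larger
clock slopes would themselves induce beta-scale heteroscedasticity (the
logistic link ties variance to the mean), blurring clock into both — a
real phenomenon, but one that would make truth labels ambiguous.

The WGBS generator places sites uniformly on a toy chromosome, draws
coverage from a negative binomial (mean 30, dispersion 5), splits reads
binomially across strands, and draws true methylation from a strongly
bimodal mixture Beta(0.6, 80) / Beta(80, 0.6).  Inside the configured
region a fraction of sites get twin-specific truths ≥ 0.5 apart; a
fraction of sites per twin get one strand's truth displaced by 0.7 (forced
strand artifacts); blacklisted sites are emitted in a matching BED.  At
30× coverage, pure read sampling also occasionally trips the >20% strand
rule at intermediate-methylation sites (~0.3% of sites), so the forced-
artifact count is verified in the tests as a paired same-seed difference
between artifact fractions 0.01 and 0.

**What the generator does not emulate** — probe-type chemistry, cell-type
mixtures, linkage disequilibrium between CpGs, genomic covariates of
methylation, realistic per-probe error heterogeneity.  Passing tests
therefore demonstrate that the statistical machinery behaves as designed
under its own assumptions (sizes, power, parameter recovery, filter
semantics), not that any particular real cohort would yield a particular
evCpG count.

## Problem sizes used in the checks

The reference cohort for parameter recovery is 200 pairs × 5000 CpGs
(seed 1); statistical-size suites use 5000 replicates (TOST at the margin,
n = 400 per side; clock regression, n = 100) and 2000 replicates (White
test, n = 727); WGBS power/null rates use 100 seeded 20 000-site pairs
each; oracle suites enumerate all 2×2 tables with total ≤ 30 plus sampled
larger ones, and compare clustering against a brute-force agglomerator at
n ≤ 8.

## Known limitations

* The equivalence test ignores the dependence of the all-pairs unrelated
  sample (guarded empirically by `independence_check`).
* Bonferroni is the only correction (deliberately conservative); FDR
  procedures, ACE/GxE variance decompositions and epigenetic-age
  predictors are out of scope.
* Lin's CCC stands in for an unspecified concordance definition; the exact
  choice does not affect discovery, only the descriptive summary.
* The discordance threshold is computed at p = 0.5; marginalizing over the
  methylation distribution would give a slightly laxer threshold.
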
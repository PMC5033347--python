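# Methods

This note documents the models, estimators and numerical choices behind
`sasbx`, and what the synthetic-data generator does and does not emulate.

## Between-sex divergence

Autosomal allele frequencies are equal in the sexes at conception, so any
divergence between adult males and females must arise within the current
generation, essentially from sex-differential viability. For a biallelic
SNP with adult frequencies `p_m`, `p_f` and zygote frequency `p` we use

    F_ST = (p_m − p_f)² / (4·p·q),   q = 1 − p.

The zygote frequency is not observable; we estimate it as the unweighted
mean `(p_m + p_f)/2`. The sexes are equally frequent at conception, and
this convention bounds the statistic by 1 (a sample-size-weighted pool
would not). The net-divergence alternative `D_a` specialises to
`(p_m − p_f)²` for a single site — it satisfies `D_a = F_ST·4pq` exactly.

Sampling alone produces divergence: with `N_m`, `N_f` alleles sampled per
sex and no selection, `E[F_ST] ≈ (1/N_m + 1/N_f)/4`. This baseline is the
neutral reference for all synthetic-data checks.

Filtering follows population-genetic practice for low-information sites: a
SNP is dropped from one population when its pooled minor allele is a
singleton there, and dropped everywhere when it is monomorphic in more than
5 populations (exactly 5 is kept). Minor-allele status is decided on pooled
(both-sex) counts within the population. Monomorphic and insufficient-data
sites propagate as missing values, never as zeros.

Per-gene summaries are the mean (default; median and maximum available) of
the per-SNP values. Genes are expected to understate selection on the
causal site because most SNPs in a gene are hitchhikers; the generator has
a `single_target_snp` mode to emulate this. The diversity proxy π is the
per-site unbiased heterozygosity `2·p̂·q̂·n/(n−1)` averaged over a gene's
SNPs (the estimator is our choice; any consistent choice works for the
π-vs-Δ descriptive analyses).

## The Δ statistic

Sex-biased expression is measured as `Δ = (m − f)/(m + f)` with `m`, `f`
per-sex summary abundances: −1 female-only, 0 unbiased, +1 male-only. For
weak bias `Δ ≈ ½·ln(m/f)`, so Δ is nearly collinear with the familiar
log₂ ratio. Replicates are averaged arithmetically per sex; when several
tissues are requested each tissue is weighted equally (mean of per-tissue
means), not by its sample count. Genes with zero total expression get a
missing Δ and are excluded from regressions. Input abundances are assumed
pre-normalized; the package does no cross-sample normalization.

## The equilibrium model

Genotype viabilities are `1 : 1 + h·S : 1 + S` per sex. The additive
effect of the focal allele is `s = [p + (q − p)h]·S`, and selection moves
the adult frequency to `p + p·q·s` to first order in `s` (the exact
genotype-frequency computation is provided as an oracle; the two agree to
`O(s²)`). The divergence produced in one generation is
`F_ST ≈ ¼·p·q·(s_m − s_f)²`.

Selection is linked to expression through `s_m = a_m·M`, `s_f = a_f·F`
with `M = ln(m+1)`, `F = ln(f+1)`: no expression in a sex means no
selection in that sex, and at high expression proportional changes in
abundance have equal fitness effects. At a sexually-antagonistic
equilibrium (`s_m = −s_f`) this collapses to

    F_ST ≈ 4·p·q·A·Δ²,   A = (a_m·a_f/(a_m + a_f))²,

valid for small |Δ|. The identity `p·q·s_m² = 4·p·q·A·(D/2)²` holds
exactly under the equilibrium construction and is property-tested. The
model also forces `F_ST → 0` at complete bias (the silent sex experiences
no selection, and at equilibrium neither does the other). Interpolating
between the small-bias quadratic and the zero endpoints yields the
Twin-Peaks shape. The singular direction `a_m → −a_f` (where A diverges
while the divergence stays finite) raises a dedicated error instructing
callers to work through the additive effects directly.

Only equilibrium-valued coefficients are supported; no multi-generation
dynamics, mutation, drift or migration. Estimating `a_m`, `a_f` from data
is deliberately out of scope.

### Load

At equilibrium the sex-specific mortality excesses are
`μ_m = 2pq(1−h_m)S_m + q²S_m` and `μ_f = 2pq·h_f·S_f + p²S_f` with `S_f`
pinned by the equilibrium condition; the per-locus load
`L_SA = ½(μ_m + μ_f)` equals the closed form
`(p + q²h_f − p²h_m)/(2[p + (q − p)h_f])·S_m` (agreement to 1e−12 is
tested). With intermediate dominance it reduces to `L_SA = s`. Loads on
independent loci combine as `1 − Π(1 − L_i)`; 100 loci at `s = 0.01` cost
63% of mean viability — the reason strong sexually-antagonistic selection
cannot be ubiquitous.

## MAP estimation of s_m

The likelihood of `(s_m, p)` given male/female counts is the product of
two binomials at the adult frequencies `p ± p·q·s_m`; the posterior of
`s_m` marginalises `p` over `(0, ½]` against a minor-allele-frequency
prior fitted as `48.4·Re[exp(−35(x−0.003)^0.7)] + 3.59(0.5−x)`. The
fractional power is evaluated on the principal complex branch for
`x < 0.003`, the only reading under which the real part is defined and the
density stays smooth and finite at 0. A flat prior is available; with
`N ≳ 1000` alleles per sex the two differ negligibly (tested).

Numerics: 512-point midpoint quadrature on `(0, ½]` (doubling changes the
posterior by < 1e−4 in practice); an 801-point uniform `s` grid on
`[−2, 2]` (empirical MAPs reach |ŝ| ≈ ½, so ±2 is safe; a boundary maximum
is flagged) with quadratic interpolation around the argmax. Counts are
internally flipped to the pooled minor allele so the prior domain applies,
and the sign convention is mapped back to the allele as designated.

The credible interval is implemented literally as the outermost grid
values where the posterior is at least 1/20 of its maximum — not an HPD
or equal-tail interval. For a near-Gaussian posterior a 1/20 density
cutoff corresponds to |z| ≈ 2.45 and therefore covers ≈ 98.6%, not 95%;
simulated coverage at `N = 2000` alleles/sex is ≈ 0.98–0.99. Users who
need calibrated 95% intervals should derive them from the returned
posterior grid instead. At field-realistic sample sizes (tens of alleles)
the intervals nearly always include 0: single-SNP estimation of `s_m` is
hopeless, which is the point of the power analysis below.

## Twin-Peaks regression

Per-gene divergence is regressed on Δ with gene × population rows as
replicates (no random-effect structure). Degree is chosen by AIC (ties to
the lower degree), with a nested LRT table alongside. The pattern test is
applied to the quartic: overall ANOVA `p < 0.05`, negative leading
coefficient, and exactly three distinct real derivative roots in `[−1, 1]`
(roots from the companion matrix; a root is real when
`|Im| < 1e−8·(1 + |Re|)`; near-equal roots collapse to one distinct root,
so a triple root at 0 is a single stationary point and fails the
criterion).

The permutation test shuffles Δ across all rows, refits the quartic and
re-evaluates the criteria; `p = (count + 1)/(n_perm + 1)`. Because the
Gram matrix of the quartic design is invariant under row permutation, each
permutation costs one 5-vector projection and a 5×5 solve. Note this
p-value is the chance rate of the composite pattern (≈ 1.5–2% for typical
data) whatever the observed signal; "detection" therefore means *both*
that the observed fit shows the pattern *and* that the chance rate is
below 5%.

The bootstrap resamples genes (not rows) with replacement to respect
within-gene correlation across populations, records the fraction of
replicates meeting the criteria, percentile CIs of the peak and valley
locations, and a gridded density of fitted curves over Δ (the heat-map
surface). Rank-deficient replicates are skipped and counted.

The small-Δ check restricts to the window between the peaks (default
(−0.52, 0.72)) and reports the quadratic coefficient, which estimates
`4·mean(pq)·A` under the model. A heterozygosity-controlled variant
regresses `F_ST/pq` (the `2pq` denominator is also exposed; the choice
only rescales the response). A penalized cubic smoothing spline with
GCV-chosen smoothing, fit to equal-count Δ-bin means, is reported
alongside the polynomial but never gates any decision. The
binary-response variant (fertility-selection candidate lists) fits a
polynomial logistic regression (AIC degree) and, in parallel, proportions
in 25 equal-count Δ bins followed by a quartic; the criteria are applied
to the binned quartic. 25 bins keeps per-bin proportions stable at
realistic gene counts.

## Per-SNP testing and power

Each SNP's 2×2 sex × allele table is tested by the exact conditional test
(default; safest at low MAF, conservative because discrete) or by the
Pearson chi-square without continuity correction (vectorised, used in
simulations). Benjamini–Hochberg replaces the original q-value machinery:
it is deterministic and assumption-light, and no qualitative conclusion
depends on the difference. Fisher's method (`−2Σln p ~ χ²(2k)`) combines
populations; zero p-values are clamped to the smallest positive float.
FDR is applied per population, with combination across populations as a
separate step.

The power analysis simulates a scan: MAFs from a chosen source, adult
frequencies `p ± pq·s`, binomial counts, chi-square p-values, BH at the
chosen level, and records the probability that *nothing* is significant.
Under the global null with well-calibrated continuous p-values this
probability equals `1 − α` exactly (BH's family-wise property under
independence); the test of that property uses moderate MAFs
(uniform 0.1–0.5) and `N = 2000` alleles/sex, where the chi-square null is
accurate — with the exact test or singleton-heavy MAFs the probability is
conservatively larger, a property of discrete tests rather than of BH.
The qualitative conclusion the module reproduces is that per-SNP detection
at genome scale is essentially impossible at realistic sample sizes even
for implausibly strong selection.

## Synthetic data

Per gene: Δ ~ uniform on [−1, 1]; SA potential `A(Δ) = A_max·(1 − Δ²)`
— the minimal smooth taper vanishing at complete bias, where the model
pins divergence to zero (the taper is configurable; no functional form is
canonical); and `s_m = 2·√A·Δ` so the identity `pq·s_m² = 4pqAΔ²` holds
exactly by construction. Each SNP draws a zygote MAF from the fitted
prior density (shared across populations); each population then
contributes independent binomial samples of `N_m` male and `N_f` female
alleles at the adult frequencies `p ± pq·s_m`. This is a within-generation
equilibrium statement, not a forward simulation — assigning `s_m` from Δ
via the identity is deliberate.

Expression: per-sample abundances are log-normal around sex means
`total·(1 ± Δ)/2` with a chosen coefficient of variation (log-normal
respects non-negativity; the real data's noise law is uncharacterised);
a silent sex yields exact zeros so Δ = ±1 is recovered exactly. Defaults:
14 male and 6 female samples, totals log-normal with median 100, CV 0.2.

Reference configuration: 3000 genes × 5 SNPs, 26 populations,
`N = 2·10⁴` alleles/sex, `A_max = 0.04` (peak additive effects
`|s| ≈ 0.2·|Δ|`, against a sampling baseline F_ST of 2.5·10⁻⁵). All
randomness flows from one seed through named substreams (delta, maf,
counts, expression, totals), so each stage reproduces in isolation.

What the generator does *not* emulate: linkage and hitchhiking structure
within genes (SNPs are exchangeable given the gene's `s_m`, except in
`single_target_snp` mode), geographic population structure (populations
share ground truth and differ only by sampling), age structure,
sex-differential migration, frequency dynamics away from equilibrium, and
any real expression normalization artefacts. Passing tests therefore show
that the pipeline recovers the model's signal under the model's own
assumptions — not that real data satisfy those assumptions.

## Problem sizes and determinism

Tests run the reference configuration with 10³ permutations/bootstraps
(rather than the 10⁵ one would use in production) and tens of replicate
seeds; detection rates and calibration probabilities are compared at
3 Monte-Carlo standard errors. Pipeline outputs are deterministically
sorted (gene, population) and written at 10 significant digits, so a rerun
with the same seed is byte-identical. The JSON report validates against
the shipped pydantic schema (`sasbx/schemas/report.schema.json`).

## Known limitations

- Between-sex F_ST cannot distinguish sexually-antagonistic from
  sexually-concordant selection; the label "SA" is a model assumption.
- The equilibrium premise (`s_m = −s_f`) makes the `s` and load estimates
  upper bounds when polymorphism is actually maintained by other forces.
- The max/20 credible interval over-covers relative to its 95% label (see
  above).
- The permutation p-value has a floor at the composite pattern's chance
  rate (~1.5–2%); it cannot be driven arbitrarily small by signal
  strength, only by more stringent criteria.
- The spline path smooths binned means, not raw rows, and is descriptive
  only.
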
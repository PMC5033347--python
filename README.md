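# sasbx

**S**exually-**a**ntagonistic **s**election and sex-**b**iased e**x**pression:
quantify ongoing sex-specific viability selection from male/female allele
counts, relate it to sex-biased gene expression, and test for the
"Twin Peaks" pattern.

## The problem

Autosomal allele frequencies are identical in males and females at
conception. If viability selection acts differently on the sexes, adult
males and females diverge within a single generation. At a biallelic SNP
this divergence is

```
F_ST = (p_m − p_f)² / (4·p·q)
```

with `p_m`, `p_f` the adult male/female frequencies of an allele and `p`
its zygote frequency (estimated as `(p_m + p_f)/2`). Sex-biased expression
is measured per gene by

```
Δ = (m − f) / (m + f)          (−1 female-only, 0 unbiased, +1 male-only)
```

A simple equilibrium model of sexually-antagonistic selection whose
strength grows with log expression predicts `F_ST ≈ 4·p·q·A·Δ²` for small
bias — where `A = (a_m·a_f/(a_m+a_f))²` is the potential for
sexually-antagonistic selection — and zero divergence both at `Δ = 0` and
at complete bias. The resulting hump-at-intermediate-bias shape ("Twin
Peaks") is detected by fitting a quartic of divergence on Δ and requiring
(i) a significant fit, (ii) a negative leading coefficient, (iii) three
real derivative roots in [−1, 1], with a permutation null and a
gene-level bootstrap for uncertainty.

The package is aimed at population geneticists working with sex-stratified
allele counts (e.g. from a variant panel plus a sample→sex map) and
paired expression atlases. It also provides: a Bayesian MAP estimator of
the per-SNP additive fitness effect `s_m` with a fitted
minor-allele-frequency prior, selection-load formulas
(`L_SA = s` for additive loci; `1 − Π(1 − L_i)` across loci), per-SNP
exact/chi-square tests with BH FDR and Fisher combination, a power
analysis for genome scans, and a synthetic-data generator with exact
ground truth so the whole pipeline is testable without any downloads.

## Worked example

Simulate a study at known ground truth and run the full pipeline
(`A_max = 0.04` puts real signal in the data; 1000 genes, 8 populations,
20 000 alleles per sex):

```yaml
# example.yaml
simulate:
  n_genes: 1000
  snps_per_gene: 5
  n_populations: 8
  N_m: 20000
  N_f: 20000
  A_max: 0.04
n_perm: 1000
n_boot: 1000
```

```
sasbx run --config example.yaml --seed 1 --out out/
```

Key lines of the printed JSON report (seed 1):

```
"coefficients": [2.63e-05, 3.27e-05, 0.00987, 4.74e-05, -0.0099]
"is_twin_peaks": true
"permutation_p": 0.016
"peaks": [-0.703, 0.709]
"peak_location_ci": {"left_peak": [-0.713, -0.694], "right_peak": [0.700, 0.718]}
"quadratic_small_delta": {"quadratic_coefficient": 0.00621, "p_value": 0.0}
"prevalence_fraction": 0.537
"detected": true
```

Reading it: the quartic has a negative leading coefficient with maxima at
Δ ≈ ±0.70 — the generator's profile `F_ST ∝ Δ²(1 − Δ²)` peaks at
±1/√2 ≈ ±0.707, so the fit recovers the truth — and the composite pattern
arises in only 1.6% of Δ-permutations. The small-|Δ| quadratic
coefficient 0.0062 estimates `4·mean(pq)·A`, and 54% of genes carry
intermediate bias (0.25 < |Δ| < 0.75). `detected` combines the observed
pattern with the permutation rate.

Library use follows scikit-learn conventions:

```python
from sasbx import TwinPeaksRegressor, SelectionMAPEstimator

reg = TwinPeaksRegressor(degree="auto").fit(delta, mean_fst)
reg.is_twin_peaks_, reg.peaks_, reg.p_anova_

est = SelectionMAPEstimator(prior="fitted").fit(counts[["n_m","N_m","n_f","N_f"]])
est.s_map_, est.ci_low_, est.ci_high_
```

Other subcommands: `sasbx simulate | fst | delta | fit | estimate-s |
power | model` (see `--help`).

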
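# snpmeta

Genotype-count meta-analysis of case-control SNP association studies.

Candidate-gene and GWAS follow-up literatures report, for each study, the
genotype counts of cases and controls at a biallelic SNP. `snpmeta` pools
such study panels: it builds the five standard genetic-model contrasts from
the counts, audits each control group for Hardy–Weinberg equilibrium (HWE),
pools with a fixed-effect Mantel–Haenszel or random-effect
DerSimonian–Laird model chosen by a heterogeneity rule, stratifies by
subgroup, and screens robustness with leave-one-out re-pooling and
funnel-plot/Egger diagnostics. It ships the compiled study panels for the
three breast-cancer risk variants in *TOX3* on 16q12 — rs3803662 (C>T, 42
datasets, 97,275 cases / 128,686 controls), rs12443621 (A>G, 15 datasets)
and rs8051542 (C>T, 15 datasets) — and a synthetic-panel generator for
calibration against known truth.

## The statistics

For a study with genotype counts (risk homozygote, heterozygote, reference
homozygote) in each arm, five 2×2 contrasts are formed: homozygote
(RR vs rr), heterozygote (Rr vs rr), dominant (RR+Rr vs rr), recessive
(RR vs Rr+rr) and allele (R vs r, 2 alleles per subject). Each table gives a
crude odds ratio OR = ad/bc with Woolf standard error
SE(log OR) = √(1/a + 1/b + 1/c + 1/d); zero cells get the +0.5
Haldane–Anscombe correction.

**Fixed effect (Mantel–Haenszel):** OR_MH = Σ(aᵢdᵢ/nᵢ) / Σ(bᵢcᵢ/nᵢ), with
the Robins–Breslow–Greenland variance for log OR_MH.

**Heterogeneity:** Cochran's Q = Σwᵢ(yᵢ − ȳ_w)² with wᵢ = 1/SEᵢ², tested
against χ²(k−1); I² = max(0, 100·(Q − df)/Q).

**Random effects (DerSimonian–Laird):**
τ² = max(0, (Q − (k−1)) / (Σwᵢ − Σwᵢ²/Σwᵢ)), weights wᵢ* = 1/(SEᵢ² + τ²).

**Model selection:** fixed MH when the Q-test P exceeds 0.1, otherwise
DerSimonian–Laird — decided independently for every contrast and subgroup.

**HWE:** 1-df Pearson χ² of observed genotypes against (np², 2npq, nq²) at
the estimated allele frequency, uncorrected.

**Egger's test:** OLS of yᵢ/SEᵢ on 1/SEᵢ; a nonzero intercept indicates
funnel asymmetry (small-study/publication bias).

## Worked example

```python
from snpmeta import load_fixture, pool_auto, summarize
from snpmeta.genetic_models import GeneticModel, build_contrast

ds = load_fixture("rs8051542")
print(summarize(ds))
# DatasetSummary(n_datasets=15, total_cases=20965, total_controls=21580)

tables = [build_contrast(s, GeneticModel.ALLELE) for s in ds.studies]
r = pool_auto(tables)
print(r.model_used, f"{r.or_value:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})",
      f"P_H={r.het.p_q:.3f} I2={r.het.i2:.1f}%")
# fixed 1.132 (1.097-1.168) P_H=0.387 I2=5.9%
```

The T allele of rs8051542 raises breast-cancer odds by ~13% per allele; the
studies are homogeneous (P_H = 0.387 > 0.1), so the fixed-effect
Mantel–Haenszel pool applies. The same call on the rs3803662 homozygote
contrast selects the random-effects model (I² ≈ 79%) and gives
1.300 (1.211–1.396).

From a shell, the same pipeline plus leave-one-out, funnel export and a JSON
run log:

```sh
snpmeta analyze --fixture rs8051542 --out reports/
snpmeta hwe --fixture rs3803662
snpmeta simulate --k 20 --or-allele 1.15 --seed 1 --out panel.tsv
```

Custom panels are plain delimited text (one study per row, six genotype-count
columns); a YAML column map adapts arbitrary headers — see
`snpmeta analyze --help`.

## The analysis scripts

`analysis/01…05` re-run the full study narrative: dataset margins and the
HWE audit, overall pooling for all five contrasts per SNP,
ethnicity-stratified pooling, leave-one-out and Egger screens, and
simulation calibration (HWE type-I error 0.052 at n = 500; pooled-CI
coverage 0.958 for a true OR of 1.15; mean Q rising 17 → 59 → 192 as the
between-study SD τ goes 0 → 0.1 → 0.2). Tables land in `results/`.

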
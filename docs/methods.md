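# Methods

## Data model

A `Dataset` is an ordered panel of independent case-control studies at one
biallelic SNP. Genotype counts are stored in the fixed order (risk-allele
homozygote, heterozygote, reference-allele homozygote), with the risk allele
declared once per dataset (T for rs3803662 and rs8051542, G for
rs12443621). Declaring orientation at the dataset level makes all five
contrasts unambiguous; re-declaring the opposite allele as the risk allele
inverts every OR exactly (tested).

The bundled TOX3 panels transcribe the per-study genotype counts compiled in
the published breast-cancer association literature. Studies that reported
genotypes separately per ethnic group enter as separate records (Stacey ×4,
Barnholtz-Sloan ×2, Barzan ×2), which is why rs3803662 carries 42 records.
The source's own overall tally for rs3803662 counts 43 analysis units; the
identity of the 43rd unit is not recoverable from the printed per-study
rows, so the panel carries the 42 that are. Reported control HWE P-values
ride along as reference metadata (`extra_labels["hwe_p_reported"]`), never
as inputs.

Transcription audit: summing the bundled counts reproduces the source's
stated margins exactly (rs3803662: 97,275 / 128,686; rs12443621: 17,750 /
19,488; rs8051542: 20,965 / 21,580), and the recomputed control HWE
P-values match the reported column to ±0.01 for 70 of 72 rows. The two
exceptions are internally inconsistent in the source itself: for He 2014
(rs12443621) the counts 115/304/201 give P = 0.998 against a reported
0.809, and for Chan 2012 the counts give P = 0.0419 against a reported
0.419 — almost certainly a misplaced decimal. The audit
(`analysis/01_dataset_overview.py`) reports both; tests assert the
recomputed values.

## Effect estimation

Crude per-study ORs from the 2×2 contrast cells: OR = ad/bc, Woolf variance
1/a + 1/b + 1/c + 1/d on the log scale. When any cell is zero, 0.5 is added
to all four cells before both the OR and the variance (Haldane–Anscombe,
the Review Manager convention), and the estimate is flagged. Tables with an
entirely empty arm are rejected — they carry no OR information. CI bounds
use z = 1.959964 (the exact normal 97.5% quantile) rather than 1.96; the
difference is below any printed precision.

The codominant homozygote and heterozygote models drop the third genotype
class rather than collapsing it, matching the usual "RR versus rr" /
"Rr versus rr" column semantics. The allele model counts 2n alleles per n
subjects as independent observations — the standard crude allele contrast,
with no within-subject correlation adjustment.

Known limitation: some source publications pooled covariate-adjusted
per-study estimates where available; those adjusted values are not in the
genotype tables and cannot be reconstructed, so this package pools crude
count-based estimates throughout. Empirically that shifts the headline
pooled ORs by ≲ 0.02 (e.g. allele-model totals 1.132 vs 1.135 published for
rs8051542), with the largest drift on rs12443621's overall contrasts, where
the crude pool is marginally significant while the adjusted mixture is not.

## Pooling

Fixed effect is Mantel–Haenszel, OR_MH = Σ(aᵢdᵢ/nᵢ)/Σ(bᵢcᵢ/nᵢ), with the
Robins–Breslow–Greenland variance for log OR_MH — the standard MH companion
(metafor's `rma.mh`, against which the implementation agrees to 10 decimal
places on the rs8051542 allele panel). A zero-cell study enters the MH sums
with the same +0.5 cells its own effect uses, keeping the two routes
consistent.

Random effects is DerSimonian–Laird: τ² = max(0, (Q − df)/(Σw − Σw²/Σw))
from the inverse-variance Q, weights 1/(SEᵢ² + τ²). With τ² truncated at
zero it reduces exactly to inverse-variance fixed pooling (tested).
I² = max(0, 100(Q − df)/Q), classified mild (<25%), moderate (25–50%),
large (>50%).

Model selection: fixed MH when the Q-test P exceeds α_het = 0.1, otherwise
DL — applied independently per contrast and per subgroup, because
heterogeneity is a property of each pooled set, not of the SNP. Q for the
rule is computed from the crude log-OR effects with inverse-variance
weights (not MH weights); at these study sizes the difference is
negligible, and it makes the selection statistic identical to the reported
heterogeneity statistic. Significance thresholds: 0.05 two-sided
everywhere, except the deliberately liberal 0.1 for heterogeneity.

## HWE testing

Pearson 1-df χ² of observed control genotypes against (np², 2npq, nq²) at
the estimated allele frequency — no Yates correction, no exact test; this
is the variant that reproduces published P_HWE columns (anchors: 0.470,
0.083). Monomorphic arms fit exactly (χ² = 0, P = 1). Out-of-HWE controls
(P < 0.05) are flagged but retained — the appropriate remedy is the
leave-one-out screen, not exclusion. Simulated type-I error at n = 500,
p = 0.3 over 10,000 replicates: 0.052.

## Robustness

Subgroups re-run the full selection-plus-pooling within each level of a
label (ethnicity, or any `extra_labels` key, e.g. user-supplied ER/BRCA
strata); single-study levels return the study's own estimate flagged
`single_study`. Leave-one-out re-pools k times with the model rule
re-applied each time. Egger's regression (OLS of yᵢ/SEᵢ on 1/SEᵢ, t-test on
the intercept with k−2 df) is reported alongside the exported funnel
points; the published analyses judged funnel symmetry visually, but a
reusable package needs the quantitative criterion. Equal-precision panels
are rejected as rank-deficient rather than returning an arbitrary fit.
The case-only ER+ vs ER− style contrast is out of scope: its table
construction is not defined by per-arm genotype counts.

## Synthetic panels

`simulate_panel` draws, per study, θᵢ ~ Normal(log OR, τ²), control
genotypes ~ Multinomial(n, (p², 2pq, q²)), and case genotypes from the
exponentially tilted probabilities ∝ (p²e^{2θᵢ}, 2pq·e^{θᵢ}, q²) — the case
genotype distribution implied by a logistic disease model with per-allele
log odds θᵢ, so the crude allele OR targets the generating OR. Defaults
(k = 20 studies, p = 0.3, OR = 1.15, τ = 0, 1000 per arm) represent a
typical well-powered follow-up panel; `size_range` draws arm sizes
log-uniformly to mimic the real panels' spread (~300 to ~23,000 subjects
per row). Everything is deterministic given `seed`.

What the simulator does not emulate: linkage disequilibrium between SNPs,
covariate confounding, genotyping error, and adjusted-estimate pooling —
so calibration results certify the estimators under the model's own
assumptions, not robustness to those violations.

Calibration sizes (chosen to estimate each rate to ~±1% while keeping the
suite fast): 10,000 replicates for the HWE type-I error; 500 panels of
k = 20 for CI coverage (observed 0.958 against the ≥ 0.93 gate); 40 panels
per τ ∈ {0, 0.1, 0.2} for Q monotonicity (observed means 17 → 59 → 192,
df = 19).

## Reporting

ORs and CI bounds print to 3 decimals; P-values below 0.001 render as
`<0.001`. Reports are plain delimited text plus a JSON run log (config,
seed, version) and are byte-identical across re-runs of the same config.
Figures are deliberately not rendered; the funnel/forest data files are the
contract, keeping the core dependency-light.
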
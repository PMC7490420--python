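# predimr

Two-sample Mendelian randomization with **exposure-only glycaemic
instruments**, plus a DerSimonian–Laird random-effects meta-analysis engine
for observational risk estimates.

## The scientific problem

Prediabetes — glycaemia above normal but below the diabetes diagnostic
threshold (e.g. fasting glucose 5.6–6.9 mmol/L) — is common, and whether it
*causes* vascular complications independently of progression to type 2
diabetes is hard to settle observationally. This package implements the
two complementary analysis arms such a study needs:

1. **Causal arm (two-sample MR).** SNPs associated with a glycaemic trait at
   genome-wide significance (P < 5×10⁻⁸) but **not** associated with diabetes
   (P > 0.05 in an independent disease GWAS) form a "prediabetes-only"
   instrument: they proxy non-diabetic glycaemic variation. After greedy LD
   clumping (r² < 0.2 within 1000 kb, lowest p retained) and
   exposure–outcome harmonization (strand flips, allele recoding,
   frequency-resolved palindromic variants), per-SNP exposure effects γⱼ and
   outcome effects Γⱼ feed the estimator battery:

   - **IVW** (plain and robust): weighted zero-intercept regression of Γ on γ
     with weights 1/σ²_Yj — β̂ = Σγ Γ/σ²_Y ÷ Σγ²/σ²_Y;
   - **MR-Egger** (plain and robust): same regression with a free intercept
     θ₀; the intercept estimates average directional pleiotropy and its test
     is the pleiotropy diagnostic;
   - **weighted median**: the weight-0.5 quantile of the per-SNP ratios
     Γⱼ/γⱼ, consistent when ≥ half the weight is valid, bootstrap SE;
   - **Cochran's Q**, leave-one-out sensitivity, and **MR-PRESSO**
     (simulation-based global RSS test, per-SNP outlier test, distortion
     test with outlier-corrected re-estimation).

2. **Observational arm (meta-analysis).** Study-level RR/OR/HR estimates are
   log-transformed (se = (ln CIᵤ − ln CIₗ)/(2·1.959964)) and pooled with the
   DerSimonian–Laird random-effects model: τ² = max(0, (Q − df)/(S₁ − S₂/S₁)),
   random weights 1/(vᵢ + τ²), with I², subgroup pooling, leave-one-study-out,
   and Begg rank-correlation / Egger regression publication-bias tests.

A seeded **synthetic-data generator** emulates every input — GWAS summary
files with known causal effect, pleiotropy, planted outliers and
strand/allele corruption; block LD; study corpora with known pooled effect
and heterogeneity — so the whole pipeline is testable end to end with
ground truth attached.

## Worked example

`examples/` contains one narrative script per capability. From
`examples/mr_analysis.py` (synthetic fasting-glucose → CAD data, true causal
OR 1.26 per mmol/L):

```
instrument construction: 128 -> 28 significant -> 25 non-disease -> 25 independent -> 25 harmonized
ivw_robust       OR 1.258 (95% CI 1.244, 1.272)  p = 0.00e+00
ivw              OR 1.259 (95% CI 1.246, 1.273)  p = 0.00e+00
weighted_median  OR 1.257 (95% CI 1.237, 1.278)  p = 2.15e-165
egger_robust     OR 1.234 (95% CI 1.186, 1.284)
  Egger intercept (OR scale) 1.002, p = 0.32  -> no directional pleiotropy if ~1, p large
Cochran's Q = 23.6 on 24 df (p = 0.48)  -> between-SNP heterogeneity
```

The staged counts show the instrument-construction accounting (128 input
variants, 28 genome-wide significant, 3 removed as diabetes-associated,
clumping and harmonization keeping 25). All three estimators recover the
simulated OR of 1.26 within their intervals; the Egger intercept near 1
with large p indicates no directional pleiotropy (none was planted).

The same flow is scriptable from a shell via the thin CLI:

```bash
predimr simulate --preset mr --seed 3 --out data/
predimr mr --config analysis.yaml
predimr meta --config analysis.yaml
predimr reproduce          # download pointers for the public GWAS files
```

## Layout

```
src/predimr/
  sumstats.py     summary-statistic and LD-table I/O, validation, presets
  instruments.py  significance filter, disease exclusion, clumping, harmonization
  estimators.py   Wald ratio, IVW, MR-Egger, weighted median, Q, leave-one-out
  mrpresso.py     global / outlier / distortion tests
  meta.py         log-effects, DL pooling, subgroups, Begg & Egger bias tests
  simulate.py     seeded generators with attached ground truth
  validation.py   simulation benchmarks (recovery, calibration, power)
  pipeline.py     two-arm orchestration from YAML config, report rendering
  cli.py          predimr {mr, meta, simulate, reproduce}
```

See `docs/methods.md` for the statistical conventions, the generator's
assumptions, and known limitations.
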
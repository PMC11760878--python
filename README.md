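# mrmediate

Two-sample Mendelian randomization (MR) with two-step mediation analysis
on GWAS summary statistics.

`mrmediate` is aimed at genetic epidemiologists asking whether an exposure
influences a disease *through* an intermediate trait — the motivating
application is the pathway from blood lipid fractions (LDL, TC, TG, APOB,
RC, ...) through leukocyte telomere length (TL) to cancer risk.  Given
three GWAS summary-statistic tables (exposure, mediator, binary outcome)
it runs the full workflow:

1. **Instrument selection and QC** — genome-wide significance
   (p < 5×10⁻⁸), greedy clumping (r² = 0.001 within 10,000 kb),
   F-statistic filter (F > 10), user-supplied confounder exclusion lists,
   and removal of variants already associated with the outcome
   (p < 1×10⁻⁵).
2. **Harmonization** — exposure and outcome effects aligned to a common
   effect allele, with EAF-based resolution of palindromic SNPs.
3. **Five MR estimators** — inverse-variance weighted (fixed/random/auto),
   MR-Egger, weighted median, simple mode, weighted mode; odds ratios with
   95% CIs; a causal call requiring directional consistency of all five
   effect estimates plus P(IVW) < 0.05 (no multiple-testing correction).
4. **Sensitivity diagnostics** — Cochran's Q, the Egger intercept test,
   a simulation-based RSS outlier test, the Steiger directionality test,
   and expected bias / type-I error under exposure–outcome sample overlap.
5. **Mediation** — stage 1 (exposure→mediator) via two-stage least squares
   on individual-level data or an intercept-including weighted summary
   regression; stage 2 (mediator→outcome) via IVW; then the product of
   coefficients with the Sobel standard error:

   B_m = B₁·B₂,  S_m = √(B₁²S₂² + B₂²S₁²),  Z = B_m/S_m,
   95% CI = B_m ± 1.96·S_m.

A synthetic-data module generates cohorts and three-trait GWAS triplets
with the assumed causal structure (SNPs → X → M → Y) and configurable
horizontal pleiotropy, confounding, and sample overlap, so every stage of
the pipeline can be validated against known ground truth.

## Worked example

Reproduce a published mediation row from its stage-1 coefficients and the
TL→lung-cancer IVW odds ratio (1.411):

```bash
mrmediate mediate --b1 8.37e-2 --s1 1.31e-2 --b2 0.3443 --s2 0.09
```

```
Bm = 0.0288179
Sm = 0.00878004
Z  = 3.2822
Pm = 0.00103
95% CI = [0.011609, 0.0460268]
```

`Bm = 0.0288` is the remnant-cholesterol → telomere-length → lung-cancer
mediated effect (log-odds scale): B₁ = 8.37×10⁻² SD TL per SD RC times
B₂ = ln(1.411) log-odds per SD TL.  (S₂ here is user-supplied, so Sm/Z
depend on it; Bm does not.)

The same computation in Python, plus a full simulated run:

```python
import numpy as np
import mrmediate as mm

m = mm.sobel_mediation(8.37e-2, 1.31e-2, float(np.log(1.411)), 0.09)
print(m.Bm)          # 0.028817798919275658

report = mm.run_pipeline(mm.PipelineConfig(
    seed=11, simulation={"n_snps": 30, "n_individuals": 15000}))
print(report.mediation[["B1", "B2", "Bm", "Sm", "Z", "Pm"]].round(4))
```

```
       B1      B2      Bm     Sm       Z      Pm
0  0.3245  0.4181  0.1357  0.043  3.1538  0.0016
```

The simulated triplet has a true mediated effect a×b = 0.3 × 0.4 = 0.12;
the run above recovers 0.136 with the Sobel 95% CI [0.051, 0.220]
covering the truth.  Estimator classes follow scikit-learn conventions
(`mm.IVW(model="auto").fit(table)` exposes `estimate_`, `se_`,
`q_pvalue_`, ...).

## Layout

- `src/mrmediate/sumstats.py` — summary-statistic I/O, validation, EAF
  completion, allele harmonization
- `src/mrmediate/instruments.py` — selection thresholds, clumping,
  F-statistics, exclusions
- `src/mrmediate/estimators.py` — the five MR estimators and causal calls
- `src/mrmediate/diagnostics.py` — Q, Egger intercept, outlier test,
  Steiger, overlap bias
- `src/mrmediate/mediation.py` — 2SLS, summary stage 1, Sobel product
- `src/mrmediate/simulate.py` — synthetic cohorts and GWAS triplets
- `src/mrmediate/experiments.py` — calibration/recovery/overlap experiments
- `src/mrmediate/pipeline.py`, `cli.py` — orchestration and the
  `mrmediate` command
- `docs/methods.md` — models, assumptions, numerical choices, limitations
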
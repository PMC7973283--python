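# bioage

Step-by-step optimization of aging-biomarker panels for biological-age
assessment.

## The problem

A biomarker of aging (BM) is a physiological or biochemical measurement that
changes systematically with chronological age (CA): pulse wave velocity,
lung capacity, accommodation of the eye, hearing threshold, and so on.
Regressing a biomarker on age and inverting the fit turns a measured value
into a **partial biological age** (BAp) — the age at which that value would
be the population norm.  A weighted combination of partial ages over a
panel of markers gives the subject's **biological age** (BA), whose
deviation from chronological age summarises how fast the person is aging.

Dozens of such panels exist, and which subset of markers to keep is the
real question.  `bioage` implements a reproducible, threshold-driven
selection pipeline for practitioners building BA panels from cohort tables
(one row per subject, missing cells allowed):

1. **Correlation screen** — drop markers with |r(BM, CA)| below a threshold
   (default 0.3), computed on pairwise-complete observations so sparse data
   still count.
2. **Redundancy pruning** — for every pair with cross-correlation
   |r| ≥ 0.7 keep one member, preferring the marker with the finer
   accuracy-in-years.
3. **Accuracy screen** — a marker changing by Δ units over a T-year
   reference interval, measured with instrument resolution δ, resolves
   Δ/δ units, i.e. dates a subject to within T/(Δ/δ) years; markers coarser
   than the gate (10 y cross-sectional, 5 y longitudinal) are dropped.
4. **Regression + outliers** — fit linear / exponential / quadratic
   BM-on-CA curves, mask values beyond k·σ of their 10-year age bin
   (single pass, default k = 3), refit, round coefficients (default 4
   decimals) and invert the monotone fit.
5. **Quality gates** — compute per-subject BA, optionally trim the extreme
   BA values, and require σ(BA−CA) < 10 years and r(BA, CA) within limits.
6. **Researcher criteria** — e.g. an interindividual-range limit (the
   classical reason to exclude body weight, which can span 45–135 kg in one
   cohort).
7. **Assembly** — weights w ∈ (0, 1] (default w = |r(BM, CA)|), and

   ```
   BA − CA = ( Σᵢ wᵢ · (BApᵢ − CA) ) / n
   ```

   over the n available members (the divisor convention used in published
   panel formulas; Σwᵢ available as the `weight_sum` alternative).

Every rejection is logged with its step, numeric evidence and threshold, so
the final panel is fully auditable.

## Worked example

No suitable public cohort exists, so the package ships a synthetic-cohort
generator whose preset mirrors the classical Soviet 13-marker screening
panel (n = 160, ages 20–70) with its known pathologies planted: a flat
breath-hold time (BHT), a weak self-assessment score (SAH), pressure and
pulse-wave markers that shadow each other (APd/APp ← APs, PWVm ← PWVe), and
a high-dispersion body weight (BW).

```python
import bioage as b

table, truth = b.generate(b.paper_like_preset(seed=1))
res = b.run(table, b.paper_like_metadata(),
            b.PipelineConfig(range_limits={"BW": 60.0}))
print(res.panel.members)
print(res.stats)
print(res.formula)
```

prints

```
['APs', 'PWVe', 'LC', 'A', 'HA', 'SB', 'WT']
CohortStats(mean=0.002, sigma=3.786, r_ba_ca=0.9651, n=160, sigma_limit=10.0)
BA-CA = (0.64 × [-131.4882 + 1.3783 × APs - CA] +
0.84 × [-17.9418 + 0.0731 × PWVe - CA] +
0.59 × [157.6849 - 0.0345 × LC - CA] +
0.66 × [8.2425 + 0.3134 × A - CA] +
0.56 × [-18.5376 + 2.3096 × HA - CA] +
0.68 × [102.0299 - 1.3307 × SB - CA] +
0.64 × [255.0546 - 2.8991 × WT - CA])/7
```

The pipeline rejected BHT and SAH at step 1 (low age correlation), APd,
APp and PWVm at step 2 (redundant), and BW at step 6 (interindividual range
above 60 kg) — exactly the planted ground truth — and the surviving
seven-marker panel dates subjects with σ(BA−CA) ≈ 3.8 years at
r(BA, CA) ≈ 0.97.

The same machinery is available as a scikit-learn estimator
(`b.PanelOptimizer(...).fit(X, y).predict(X)`) and from the shell:

```bash
bioage simulate --seed 1 --out cohort.csv --truth-out truth.json
bioage run cohort.csv --report report.json      # exit 0 accepted, 2 rejected
bioage screen cohort.csv --threshold 0.3
```

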
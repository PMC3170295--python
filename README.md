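# nabiassim

How much spurious correlation between self-reported work stress and
self-reported mental health can **negative affectivity (NA) bias alone**
produce?

Cross-sectional questionnaire studies of occupational stress often measure
both the exposure — here Siegrist's effort–reward imbalance (ERI) — and the
outcome — here the 12-item General Health Questionnaire (GHQ-12) — by
self-report. A respondent with high negative affectivity tends to answer
*both* instruments pessimistically, which can inflate the observed
exposure–outcome correlation even when no true relationship exists.
`nabiassim` quantifies that worst case by simulation, giving researchers a
yardstick: *how prevalent and how intense would NA have to be to account
for the R² I observed?*

## The model

Null populations of n subjects are generated item by item: each of the 29
items (6 effort, 11 reward, 12 GHQ) is drawn independently from its own
marginal distribution, so by construction there is **no** relationship
between the stressor items and the mental-health items. Marginals can be
estimated from a real response matrix, or reconstructed by moment matching
(discretized truncated normals calibrated so the implied scale-level
moments equal the built-in baselines: effort 12.5 (SD 1.9), reward 48.1
(SD 3.2), log GHQ score 2.29 (SD 0.20)).

NA is injected with two knobs: each subject carries the trait with
probability *p*, and for a trait carrier each item is independently
affected with probability *q*. Every affected response is moved one level
in its "negative" direction — effort and GHQ up, reward down — saturating
at the scale boundary.

Each population is then scored,

- effort score E = sum of 6 items (6–30),
- reward score R = sum of 11 items (11–55),
- ERI ratio = E / (R · 6/11)  (the 6/11 factor corrects the unequal item counts),
- GHQ Likert score = sum of 12 items (0–36),

and three OLS regressions of log GHQ score are fitted per population: on
the log ERI ratio, on the raw ratio, and on effort and reward jointly.
Across many populations per (p, q) cell the package reports the mean
unadjusted R² and the proportion of populations with a significant
(p < 0.05) coefficient — the spurious "effect" the bias alone creates.
Under the null with no NA these calibrate analytically: type-I error 0.05
per coefficient and E[R²] = k/(n−1).

## Worked example

```python
from nabiassim import (NAConfig, RunConfig, build_reference_marginals,
                       interpret_r2)
from nabiassim.experiment import run_grid
from nabiassim.inference import ModelId

marginals = build_reference_marginals()
config = RunConfig(n_subjects=300, n_populations=500, master_seed=42,
                   p_grid=(0.0, 0.05, 0.2), q_grid=(0.0, 0.2, 0.4))
grid = run_grid(config, marginals)
for cell in grid:
    st = cell.model_stats[ModelId.LOG_RATIO]
    print(f"p={cell.p_subject:.2f} q={cell.q_items:.2f}  "
          f"mean R2={st.mean_r2_pct:5.2f}%  "
          f"prop significant={st.prop_significant['log_eri_ratio']:.2f}  "
          f"mean ERI ratio={cell.score_means['eri_ratio']:.3f}")
verdict = interpret_r2(6.0, grid)
print(f"band = {verdict.band}; weakest NA settings: {verdict.minimal_cells}")
```

prints

```
p=0.00 q=0.00  mean R2= 0.32%  prop significant=0.04  mean ERI ratio=0.479
p=0.00 q=0.20  mean R2= 0.32%  prop significant=0.04  mean ERI ratio=0.479
p=0.00 q=0.40  mean R2= 0.32%  prop significant=0.04  mean ERI ratio=0.479
p=0.05 q=0.00  mean R2= 0.32%  prop significant=0.04  mean ERI ratio=0.479
p=0.05 q=0.20  mean R2= 0.47%  prop significant=0.09  mean ERI ratio=0.482
p=0.05 q=0.40  mean R2= 1.87%  prop significant=0.56  mean ERI ratio=0.486
p=0.20 q=0.00  mean R2= 0.32%  prop significant=0.04  mean ERI ratio=0.479
p=0.20 q=0.20  mean R2= 1.67%  prop significant=0.53  mean ERI ratio=0.493
p=0.20 q=0.40  mean R2=10.82%  prop significant=1.00  mean ERI ratio=0.509
band = possibly_na_unlikely; weakest NA settings: ((0.2, 0.4),)
```

Reading it: with no NA (any cell with p=0 or q=0) the regression finds a
"significant" association in ~5% of populations — the nominal false-positive
rate — and mean R² sits at the null expectation 1/(n−1) ≈ 0.33%. With NA in
20% of subjects affecting 40% of items on average, the bias alone yields a
significant coefficient in essentially every population and a mean R²
near 11%, while the mean scores themselves barely move (ERI ratio
0.479 → 0.509). An observed explained variance of 6% falls in the
"possibly NA, but unlikely" band, and the weakest simulated NA
configuration reaching it is (p=0.2, q=0.4).

The same sweep is available from a shell:

```sh
nabiassim run --n-populations 500 --seed 42 --p-grid "0 0.05 0.2" \
    --q-grid "0 0.2 0.4" --out-dir out/
nabiassim interpret --r2 6 --grid out/results_long.csv
nabiassim calibrate --out reference_marginals.csv
```

`run` writes `table1.csv` (R² and proportion-significant per model),
`table2.csv` (mean (SD) of the four derived scores), a full-precision
`results_long.csv` and a `manifest.json` capturing the configuration.

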
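# mhtrends

Quantifying research interest in mental-health (MH) conditions within
clinical-trial registries by mining trial description text. The package
reads per-trial registry study records (legacy `clinical_study` XML, one
file per trial), screens them by lifecycle status and start-year window,
normalizes and tokenizes the brief + detailed description blocks, counts a
small lexicon of MH terms — by default *depression*, *anxiety*,
*loneliness*, *distress* — per trial, and models how the odds of mentioning
each term have changed over calendar time and across the COVID-19 pandemic
boundary.

It is written for epidemiologists and meta-researchers who treat term
mentions in trial summaries as a proxy for research attention, and who need
the whole chain — text dialect, screening accounting, model battery — to be
reproducible and testable without touching the live registry.

## The model core

For each term *t* and trial *i*, the outcome is the binary mention flag
$y_{it} = \mathbf{1}\{\text{count}_{it} \ge 1\}$ (counts use exact token
equality after normalization; the per-trial frequency is
$\text{count}_{it}/\text{total words}_i$). Two logistic layouts are fit by
iteratively reweighted least squares (Newton–Raphson on the Bernoulli
log-likelihood), implemented from first principles in
`mhtrends.trend_models`:

* **period + completion**:
  $\operatorname{logit} P(y_{it}=1) = \beta_0 + \beta_1\,\text{covid}_i + \beta_2\,\text{complete}_i$,
  where `covid` = 1 for start year ≥ 2020 and `complete` = 1 for status
  "Completed";
* **year trend**:
  $\operatorname{logit} P(y_{it}=1) = \beta_0 + \beta_1\,\text{year}_i$,
  with the start year untransformed so $e^{\beta_1}$ is the per-year odds
  multiplier.

Inference: SEs from the inverse observed information, Wald $z^2$ statistics
(chi-square, 1 df), 95% CIs $\exp(\hat\beta \pm 1.96\,\mathrm{SE})$, and a
per-covariate likelihood-ratio test from refitting without that covariate.
The battery also includes Pearson year-trend correlations per status,
sensitivity/specificity of the binary covariates for each mention outcome,
variance inflation factors, and sample skewness/kurtosis of the flags.

A synthetic registry generator (`mhtrends.synth`) with a known logistic
ground truth — including decoy tokens such as `anxiety-related` and
`patient's` that a correct tokenizer must not count — makes every stage
verifiable end to end.

## Worked example

```sh
python analysis/01_simulate_registry.py --seed 1   # registry XML -> scratch/
python analysis/02_extract_dataset.py              # screen + profile
python analysis/03_fit_trend_models.py             # both model layouts
```

which prints (seed 1):

```
screened 2723 -> 2262 trials
modelled 5 outcomes on 2262 trials
  depression  pandemic-period OR     0.944 (p=0.774);  per-year OR 1.009 (Wald 0.65, p=0.419)
  anxiety     pandemic-period OR     9.548 (p=0.000);  per-year OR 1.242 (Wald 34.08, p=0.000)
  loneliness  pandemic-period OR 40716948963996904.000 (p=0.000);  per-year OR 1.568 (Wald 4.83, p=0.028)  [separation: OR unreliable]
  distress    pandemic-period OR     4.165 (p=0.000);  per-year OR 1.126 (Wald 13.94, p=0.000)
  any_word    pandemic-period OR     2.602 (p=0.000);  per-year OR 1.057 (Wald 31.37, p=0.000)
strongest year trend: anxiety among Completed trials (r = 0.634)
```

Reading this: of 2723 generated trials, 2262 survive status/window
screening. Anxiety mentions are strongly associated with the pandemic
period (odds ratio 9.5) and rise about 24% per year in this simulation;
depression shows no trend. The loneliness period model hits
quasi-separation — the term is rare and almost exclusively post-2020 — so
its Wald odds ratio explodes and the fit is flagged rather than suppressed,
which is exactly how plain maximum likelihood behaves on such data.
`analysis/04_diagnostics.py` adds sensitivity/specificity (the pandemic
flag is specific, ~76–78%, but insensitive; completion is the reverse),
VIFs, and the right-skewed/leptokurtic moment signature of rare flags, and
`analysis/05_parameter_recovery.py` verifies that both layouts recover
known generating coefficients with nominal CI coverage.

The same battery runs on real exports: `mhtrends extract --xml-dir ...
--index ... --out dataset.csv` then `mhtrends analyze --dataset dataset.csv
--out report/` (use `--archive-format` for externally archived per-trial
tables).

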
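# Methods

## Problem and data model

The unit of analysis is one registered clinical trial: an identifier
(`NCT` + 8 digits), a lifecycle status label, a start date, and two
free-text blocks (brief and detailed description). The scientific question
is whether the odds that a trial's description mentions a given
mental-health term have changed with calendar time and across the COVID-19
pandemic boundary, treating mentions as a proxy for research attention.
Everything is computed per trial first (counts, frequencies, binary
mention flags) and modelled second; no step depends on the live registry.

## Text dialect

The normalization/tokenization dialect is fixed, not configurable, because
the term statistics are only comparable across datasets under one dialect:

* every character that is not a Unicode letter, digit, whitespace,
  apostrophe or dash is replaced by **one** space (so removed punctuation
  never fuses adjacent words); text is lowercased;
* typographic apostrophes (`’`) fold to `'`, en/em dashes to `-`, before
  any other rule, so the kept-set and the possessive rule each see one
  spelling; underscore is treated as a symbol, not a word character;
* tokens are whitespace runs; a word-final `'s` is stripped (so
  "alzheimer's" ≡ "alzheimer"); a bare trailing apostrophe (plural
  possessive) is kept; tokens emptied by stripping are dropped;
* the brief and detailed blocks are concatenated brief-then-detailed with a
  single separating space and tokenized jointly, so one total word count is
  the denominator for all of a trial's term frequencies. Processing the
  blocks separately is the one defensible alternative; joint processing was
  chosen because the frequency outcome is defined against "the text of the
  trial", and the switch is a single line in `textprep.prepare`.

Letters are Unicode letters (registry texts contain accented drug and
author names); ASCII input behaves exactly per the rules above. The
normalizer is idempotent, which the property tests exercise on arbitrary
strings.

## Term matching

Matching is exact token equality against a validated lexicon (each term
must itself survive the dialect unchanged). Inflected or derived forms
(`depressive`, `anxious`, `lonely`) and hyphenated compounds
(`anxiety-related`) deliberately do **not** count: the outcome is the
appearance of the condition's name, and widening the match set would change
every downstream estimate. A stem-expanded lexicon can be supplied in
config where that is the question. Trials with empty descriptions get
frequency 0 (not missing) plus a degenerate flag, so they remain in
mention-based regressions as non-mentions and the modelled n equals the
screened n.

## Screening

Included statuses: Recruiting, Enrolling by invitation, Completed, Active
not recruiting. Excluded: Available, Withdrawn, Unknown status, Terminated,
Suspended, Not yet recruiting, No longer available. Matching is on a
lowercased, whitespace-collapsed normal form. The study window is start
year 1988–2022 and uses the year only. Per record the bucket order is:
excluded status → unresolvable start year → out-of-window year → included;
the report balances by construction (input = included + Σ exclusions +
bad-date), and unknown status labels are a hard error by default so
registry vocabulary drift is caught rather than silently dropped.

## Statistical battery

Logistic fits use Newton–Raphson/IRLS on the Bernoulli log-likelihood,
convergence when the largest coefficient step is below 1e-8 (cap 100
iterations), optional frequency weights for grouped data. SEs come from the
inverse observed information at the optimum; Wald statistics are reported
as z² (chi-square with 1 df, the convention of mainstream commercial
packages) with plain z behind a flag; CIs are exp(B ± 1.96·SE) using the
normal quantile; per-covariate LRTs refit without that covariate and refer
2·(LL_full − LL_reduced) to chi-square(1). No penalization (Firth or
otherwise) is applied under quasi-separation: rare, late-appearing terms
genuinely produce exploding plain-MLE odds ratios, and the fit is flagged
(`converged = False`, slope magnitude > 30 on any *slope*; the intercept is
exempt because start year enters untransformed, making a large intercept
legitimate) while values are still reported. Start year is not centered;
centering would change only the intercept.

Pearson year-trend correlations default to per-year-mean mode (year vs the
mean frequency of that status's trials in that year); per-trial mode is
available. With very few year points the per-year-mean r is fragile and can
reach ±1 exactly — expected behaviour, reported as computed.
Sensitivity/specificity treat the binary covariate as the diagnostic test
and the mention flag as the condition; this orientation makes the pandemic
flag's specificity approximately the pre-2020 share of trials, a useful
interpretive anchor. VIFs are 1/(1−R²) from OLS of each predictor on the
rest; moments are central-moment g1 and excess g2, whose Bernoulli limits
(1−2p)/√(p(1−p)) and (1−6p(1−p))/(p(1−p)) explain the right-skewed,
leptokurtic signature of rare mention flags.

## Synthetic registry

The generator emulates the statistical shape of a registry export, not its
language. Defaults, chosen once as the study conditions:

* volumes: `round(13·e^{0.085(year−1988)})` trials per year over 1988–2022
  (≈2720 generated, ≈2260 after screening — the scale of a single-condition
  registry query);
* status mix ≈ 66% Completed among included statuses, with every excluded
  status present so screening is exercised; the "Available" category
  carries a missing start date, as that category does in real exports;
* description length lognormal, median 120 words, σ = 0.6; 2% of trials
  have no description at all;
* per-term mentions from
  `logit P = α_t + β_year·(year−2000) + β_covid·covid + β_complete·complete`,
  with occurrence count 1 + Poisson(0.5) once mentioned. Baselines α_t are
  calibrated against the volume curve so the marginal mention rates sit at
  depression ≈ 6.5%, anxiety ≈ 2.8%, loneliness ≈ 0.4%, distress ≈ 2.1% —
  the common-term/rare-term spread the four conditions show in registry
  text. Year/period/completion effects use registry-scale values; for
  loneliness, whose marginal single-covariate estimates are inflated by
  quasi-separation, moderated joint values (β_year = 0.10, β_covid = 2.5)
  are used because the marginal values cannot coexist in one logit that
  stays inside (0,1) over the window;
* decoys (`anxiety-related`, `patient's`, `anxious`, …) and random
  punctuation/casing dressing are injected so that the tokenizer/matcher
  contract is load-bearing: the pipeline must recover the generated mention
  flags exactly, and the tests assert 100% agreement;
* one RNG stream per trial, seeded by (registry seed, trial index), so
  output is byte-identical per seed and independent of generation order.

What the generator does **not** model: clinical language, phrase structure,
duplicate submissions, status transitions over time, or any correlation
between description length and mention probability. Passing tests therefore
demonstrate the pipeline and the estimators, not robustness to real-world
text idiosyncrasies beyond the punctuation/possessive/compound cases
injected deliberately.

## Recovery experiments

`recovery_experiment` regenerates the registry per replicate (seed base+i),
refits, and summarises bias, RMSE and 95% CI coverage per coefficient.
Estimates are compared against same-name generative values, so the
generating term model must match the fitted layout: marginal logistic
layouts are non-collapsible, and a year trend left in the generative model
biases the period-indicator fit through the year–period correlation (and
vice versa). The experiment supports the full text pipeline per replicate
and a flags-only mode that draws mention flags from the same logistic model
without prose; the two are statistically interchangeable because the text
round trip is exact (verified separately at 100% flag agreement), and the
flags mode is used for replicated experiments, at 2000 trials and 200–300
replicates, to keep them at desk scale.

## Numerical and degenerate-input choices

* Single-class outcomes raise; callers that sweep outcomes skip the term
  with a warning instead of failing the batch.
* A near-singular information matrix gets a 1e-10 ridge (warned); a
  singular one at the optimum falls back to the pseudo-inverse (warned).
* Odds-ratio exponentials overflow to `inf` rather than raising, so
  separation produces a flagged-but-inspectable result.
* Frequencies are written to CSV at full float precision, so the dataset
  round-trips bit-exactly through its reader.
* Dates without a day parse as day 1; only the year is used. Unparseable
  dates are rejected at screening (with their own report bucket), never
  guessed.

## Known limitations

* Exact-token matching undercounts conditions referred to by synonyms or
  derived forms; that is a definition, not an oversight, but it bounds
  interpretation.
* Plain MLE under quasi-separation yields unusable point estimates for
  rare terms in short windows; the flag tells you when, and the LRT p-value
  remains informative when the Wald machinery degrades.
* Per-year-mean Pearson r with few occupied years is unstable; prefer the
  logistic year-trend model for inference and treat r as descriptive.
* The archive adapter maps external per-trial tables by header heuristics;
  tables without per-term counts lose the frequency-based analyses
  (mention-based models still run).
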
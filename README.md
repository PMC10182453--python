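# rdsentinel

Estimating rare-disease (RD) incidences from search-engine query logs.

Rare diseases are hard to surveil through clinical registries: diagnosis is
slow, cases are scarce, and reporting is fragmented across departments.
Search logs offer a complementary signal — patients and families search for
disease names, causal genes, and treatments before and after seeking care.
The raw volume of disease-related queries, however, is a poor proxy for
incidence: most of it comes from curiosity, homework, cyberchondria and,
above all, news. A celebrity diagnosis or an awareness day multiplies
search volume without a single new case.

`rdsentinel` implements a two-step method that addresses this:

1. **Session intent prediction.** Queries matching *level-1* RD keywords
   (names, genes, specific treatments) anchor *sessions* — maximal runs of
   one user's queries with inter-query gaps of at most 30 minutes. Each
   session is classified as **RD-concerned**, **news-concerned**, or
   **other** by an LSTM over the per-query feature sequence combined with a
   38-dimensional session vector (statistical features plus
   intent-specific word/URL indicators, including a word-frequency burst
   statistic C(w,t) = (n(w,t)+α) / (Σⱼ n(w,tⱼ)/K + α)).
2. **Incidence estimation.** RD- and news-concerned session counts
   x_sd(dᵢ, lⱼ, tₖ) and x_sn(dᵢ, lⱼ, tₖ) per disease dᵢ, region lⱼ and
   season tₖ feed linear estimators of the (rescaled) incidence. The
   richest variant factorizes coefficients by disease and region:

   ŷ(dᵢ, lⱼ, tₖ) = α_d(dᵢ)θ_d(lⱼ)·x_sd + α_n(dᵢ)θ_n(lⱼ)·x_sn + β(dᵢ)Φ(lⱼ)

   fitted by Adam on MSE with early stopping on a chronological
   validation year; evaluation uses RMSE and the relative error rate
   RER = Σ|ŷ−y| / Σy. The news term carries mostly *negative* weights —
   it subtracts news-driven search volume that carries no incidence signal.

Because real query logs and the clinical registry are proprietary, the
package ships a first-class synthetic world generator
(`rdsentinel.simulate`) with known ground truth: planted keywords, session
boundaries, intents, news bursts, and rank-1 generating coefficients. All
tests and the acceptance script run against it.

## Worked example

Generate a world, build sessions, and compare estimator variants:

```bash
rdsentinel simulate --users 800 --seed 5 --out demo
rdsentinel sessionize --logs demo/logs.tsv --lexicon demo/lexicon.tsv --out demo/sessions.jsonl
rdsentinel fit --panel demo/panel.csv --variant spec_dl --input session --seed 0 --out demo/fit.json
rdsentinel report --panel demo/panel.csv --seeds 3 --out demo/report.md
```

which prints

```
wrote 2924 records to demo/logs.tsv
1022 sessions from 2924 records
{"rmse": 0.006525377758399127, "rer": 0.05652569513312354}
```

and writes a comparison table (test-year metrics, mean over 3 seeds with
95% t-intervals; P from a two-sided Welch test of query vs session input):

| Model | Input | RER (95% CI) | RMSE (95% CI) | P (RER) |
|---|---|---|---|---|
| general | query | 1.057 (1.046-1.069) | 0.138 (0.138-0.138) | 6.5e-06 |
| general | session | 0.146 (0.145-0.148) | 0.024 (0.024-0.024) |  |
| spec_d | query | 1.117 (1.114-1.119) | 0.140 (0.137-0.142) | 1.73e-08 |
| spec_d | session | 0.092 (0.092-0.093) | 0.012 (0.012-0.013) |  |
| spec_dl | query | 1.125 (1.122-1.128) | 0.139 (0.137-0.142) | 5.53e-08 |
| spec_dl | session | 0.057 (0.056-0.057) | 0.007 (0.006-0.007) |  |

Reading the table: raw query counts (the classic infoveillance input)
barely track incidence in a world with news bursts and off-target search
volume — RER near 1 means errors as large as the signal. Intent-filtered
session counts cut the test-year RER by an order of magnitude, and the
disease×region factorization (`spec_dl`) is the strongest variant.

The same objects are available as a library — `Lexicon`, `build_sessions`,
`SessionFeaturizer`, `IntentClassifier`, `aggregate_panel`,
`IncidenceRegressor` — following scikit-learn fit/predict conventions.

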
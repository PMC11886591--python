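# readerstudy

Analysis toolkit for **multi-reader multi-case (MRMC) diagnostic accuracy
studies with a consensus ground truth** — the setting in which a panel of
imperfect observers (e.g. veterinary radiologists plus a commercial AI
reader) each labels radiographic findings *normal* or *abnormal*, and no
external reference standard exists.

It is aimed at researchers evaluating diagnostic software or reader
panels who need the full chain from raw long-format assessments to
publication-style performance tables, plus a synthetic panel generator so
the whole pipeline can be exercised and validated without any data.

## The method

Each finding *f*<sub>*j,k*</sub> (study *j*, finding code *k*) is binary:
normal (0) or abnormal (1). Reports only state some findings explicitly;
a finding raised by any reader of a study but unmentioned by another
reader of the same study is imputed as a normal call by that reader.

**Consensus ground truth.** With assessments *f̂*<sub>*j,k,i*</sub> from
the *n* ≥ 5 observers who read the study,

&nbsp;&nbsp;&nbsp;&nbsp;*f*<sub>*j,k*</sub> = 𝕀( (1/n) Σ<sub>i</sub> *f̂*<sub>*j,k,i*</sub> ≥ 0.5 )

i.e. the median observer decides and exact ties count as abnormal.
Findings with fewer than five assessments are excluded and logged.

**Observer metrics.** Each assessment is a TP/TN/FP/FN relative to the
consensus; accuracy, sensitivity and specificity are micro-averaged
(counts pooled over all findings the observer assessed, then divided).
A metric with an empty denominator is *undefined*, rendered `-`, never
coerced to zero. The floor every observer should beat is the
always-normal benchmark: constantly guessing "normal" scores an accuracy
equal to the prevalence of consensus-normal findings.

**Ambiguity strata.** Inter-observer disagreement per finding is
*V*<sub>*j,k*</sub> = (1/n) Σ<sub>i</sub> (*f̂*<sub>*j,k,i*</sub> − *f*<sub>*j,k*</sub>)²,
the fraction of observers in the minority. Unanimous findings have
*V* = 0 exactly; non-unanimous findings strictly below / above the
median positive variance form the low- / high-ambiguity strata (findings
exactly at the median belong to neither and are reported separately).

**Comparisons.** Every human is compared to the AI on each metric with a
pooled two-proportion z-test, Bonferroni-corrected within one metric ×
one subsample family; observers are compared to the guessing benchmark
with a one-proportion z-test. Adjusted p < 0.05 is significant; tables
carry `*`/`**`/`***` stars at adjusted 0.1 / 0.05 / 0.01.

## Worked example

Simulate a study-scale panel (50 studies, 11 radiologists each reading
about half of them, one AI reading all, ~16k observer-level findings)
and analyze it in one command:

```bash
readerstudy demo --seed 1 --out demo/
# studies=50 observers=12 observer-level findings=17006 benchmark accuracy=0.7900
```

`demo/metrics_all.csv` holds the all-findings performance table, sorted
by accuracy descending with the AI row flagged:

```
observer_id,is_ai,accuracy,sensitivity,specificity,...
R01,False,0.8514335360556038,0.738589,0.881319,...
AI,True,0.8435237329042639,0.653333,0.894442,...
R02,False,0.8370913190529876,0.720109,0.867710,...
```

Here the AI's accuracy (0.844) sits between the best and second-best
radiologist, it is less sensitive (0.653) but more specific (0.894) than
most humans — the qualitative signature this kind of panel produces.
`demo/distribution.csv` shows the subsample composition:

```
,all,no_unanimity,low,high
normal_pct,78.99...,74.51...,84.31...,64.75...
abnormal_pct,21.00...,25.48...,15.68...,35.24...
n_observations,17006.0,12421.0,6007.0,6081.0
```

The abnormal share rises from the low- to the high-ambiguity stratum:
disagreement concentrates on abnormal findings because observers are
less sensitive than they are specific. Every observer beats the 79.0%
always-normal benchmark. The remaining outputs are the per-stratum
metric tables, the test results CSVs (`tests_vs_ai.csv`,
`tests_vs_benchmark.csv`) and a `run_log.json` with exclusion counts and
the imputed fraction.

Analyze your own data with

```bash
readerstudy analyze --findings F.csv --design D.csv --registry obs.yaml --out out/
```

where `F.csv` has header `study_id,finding_code,observer_id,assessment`
(assessment ∈ {0,1,normal,abnormal}), `D.csv` has
`observer_id,study_id`, and `obs.yaml` names the AI observer id.

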
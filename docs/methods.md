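# Methods

## Setting and model

A multi-reader multi-case study produces, for each radiographic study
*j*, a set of coded findings *k*, each labelled normal (0) or abnormal
(1) by every observer *i* who reported on that study. The reading
design is incomplete by construction: each human reads only a subset of
studies, while an optional AI observer reads all of them. There is no
external reference standard; the true state of a finding is proxied by
the panel consensus.

Three modelling conventions shape everything downstream:

1. **Per-study finding universe.** The codable vocabulary of a study is
   the union of finding codes raised by *any* of its readers. A code
   nobody raised for a study simply does not exist for that study. This
   is what produces the characteristic class imbalance (~80–85% normal
   observations): most findings are raised by one reader and imputed
   normal for the rest.
2. **Unmentioned means normal.** A reader who did not mention a finding
   in the universe of a study they reported is taken to have judged it
   normal. Imputed records carry `mentioned=False` so the imputed
   fraction is reportable; imputation is idempotent and never alters an
   explicit record.
3. **Consensus with ties to abnormal.** The consensus is
   𝕀(mean ≥ 0.5) over the n ≥ 5 observers of the finding. The ≥ in the
   indicator is load-bearing: with an even panel an exact split is
   called abnormal. Findings with n < 5 are excluded and logged, not
   force-labelled. The AI participates in the consensus by default,
   exactly like a human; `exclude_ai_from_consensus=True` restricts the
   panel to humans (this choice mildly affects the AI's measured
   specificity, which is why it is a visible switch).

## Metrics and comparisons

Accuracy, sensitivity and specificity are micro-averaged: TP/TN/FP/FN
are pooled over every finding the observer assessed before dividing.
Observers therefore have different denominators (humans ~half the
studies, AI all of them). Empty-denominator metrics are UNDEFINED
(`None`, rendered `-`), never zero — an observer whose studies happened
to contain no consensus-abnormal finding has no sensitivity, which also
removes them from that metric's ranking and shrinks the Bonferroni
family.

Best/median/worst human are re-determined per metric. With h defined
values sorted descending, the median is the element at 1-based position
⌈h/2⌉ (the 6th of 11; for even h this selects the larger of the two
middle values; `median_position="floor"` selects the other).

Human-vs-AI comparisons use the unpaired pooled two-proportion z-test on
each observer's own numerator/denominator; the family for Bonferroni
correction is all humans tested for one metric within one subsample.
The test ignores that observers overlap on findings and that the
consensus itself contains each observer's vote; with ~12 readers the
self-vote weight is small, and the null simulations below measure the
realised error rate rather than assuming it. Comparisons against the
always-normal benchmark use a one-proportion z-test with the null
variance taken at the benchmark prevalence. All tests are two-sided. A
test whose pooled proportion is 0 or 1 is degenerate and reported as
p = 1 with a flag.

## Ambiguity stratification

Disagreement per finding is the variance of assessments about the
binarized consensus, V = (1/n) Σ (f̂ᵢ − f)², which for binary data is
the minority fraction: 0 under unanimity, 0.5 at an even split. A
mean-reference mode (population variance about the mean assessment) is
provided as an opt-in alternative because the two readings of the
statistic differ at split panels (0.5 vs 0.25 for a 3–3 split) and
neither dominates on first principles; the consensus reference is the
default because it is the form the outcome classification already uses.

Non-unanimous findings strictly below the median positive variance are
LOW ambiguity, strictly above are HIGH, and findings exactly at the
median form an explicit AT_MEDIAN bucket belonging to neither stratum.
The strict split is deliberate: it is the only reading under which low
plus high observation counts can fall short of the non-unanimous total,
which is what incomplete designs produce in practice. The median is
taken over unique findings by default; `median_scope="observations"`
weights it by each finding's observer count instead. Stratum membership
of a finding applies to all observer-level observations of it.

## Synthetic panel generator

The generator emulates the study design the analysis assumes: 50
studies, Poisson(51) findings each, 11 humans reading each study
independently with probability 0.5 (≈25 reports each), one AI reading
everything, 16% latent abnormal prevalence — together ≈16.4k
observer-level findings. Default observer profiles span Se 0.64–0.95
and Sp 0.80–0.94 with the usual inverse coupling, and the AI profile
(Se 0.688, Sp 0.944) is more specific and less sensitive than most
humans.

Each finding has a difficulty d ∈ [0, 1]; an observer with class-
appropriate skill q labels it correctly with probability
(1 − d)·q + d·0.5 — difficulty mixes judgement with a fair coin. This
one-parameter corruption keeps a closed form for recovery tests while
generating the unanimous / low / high variance structure. By default
half the findings are unambiguous (d = 0) and the rest draw
d ~ U(0.1, 0.6). Abnormal calls are always mentioned; normal calls are
mentioned with probability 0.3, exercising the imputation path the way
real reports (silent about normal anatomy) do. Reader sets are redrawn
until every study has at least 5 readers so the consensus gate can be
met; latent truth is emitted separately from the finding table so the
analysis never sees it.

What the generator does **not** emulate: correlated errors between
observers (e.g. shared training), finding-level difficulty that depends
on the true state, per-study case mix, or observers whose skill drifts
over the reading session. Passing tests therefore demonstrate the
pipeline's arithmetic and its statistical calibration under independent
errors, not robustness to reader correlation — on real panels the
unpaired z-test's error rate is not guaranteed by these simulations.

A consequence worth noting: the consensus abnormal share of a generated
panel (~21%) exceeds the latent 16%, because studies lose
never-mentioned all-normal findings from their universe and even-panel
ties break toward abnormal. The same mechanism operates in real coded
report data.

## Numerical and design choices

- Analysis is fully deterministic; all randomness lives in the
  generator behind one integer seed (NumPy `default_rng`).
- Variances are compared to the median with exact float equality; the
  values arise from identical integer ratios, so findings tied with the
  median variance are detected reliably when the positive-variance count
  is odd. With an even count the median is an average of two distinct
  values and the AT_MEDIAN bucket is empty, which is correct behaviour.
- Table ordering is accuracy-descending with observer id as the
  deterministic tie-break; re-running the pipeline on its own emitted
  CSVs reproduces the bundle byte-for-byte.
- Problem sizes in the validation suite: parameter recovery uses 5,000
  findings × 6 readers; calibration of the corrected comparisons uses
  200 null panels of 500 findings each. These sizes give binomial
  standard errors small enough for 3-SE assertions while keeping the
  whole suite fast on a single CPU.

## Known limitations

- With an even reader panel, the tie-to-abnormal rule makes consensus
  recovery of a latent truth asymmetric: at 6 readers with 10% error, a
  normal-truth finding is mislabelled with probability
  P(Bin(6, 0.1) ≥ 3) ≈ 0.0159 versus P(Bin(6, 0.1) ≥ 4) ≈ 0.0013 for an
  abnormal-truth finding, capping expected agreement near 98.6% at 84%
  normal prevalence. Odd panels have no such ceiling. The suite asserts
  the exact binomial closed form for this.
- The unpaired two-proportion test neither models reader overlap nor
  the self-vote in the consensus; paired/clustered MRMC variance models
  (Obuchowski–Rockette, DeLong) are out of scope.
- The guessing benchmark and all prevalences are properties of the
  consensus, itself an imperfect proxy — most fragile exactly where
  ambiguity is high.
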
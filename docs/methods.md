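# Methods

## Scope and model

`confcal` analyses tables of dichotomous risk-assessment judgments, each
accompanied by a 0–100 confidence rating, produced by a cohort of judges
(here: nurse students and experienced nurses judging whether a simulated
patient is at risk of a critical event). The package computes the
classical binned decomposition of judgment quality, builds reliability
diagrams, labels scenario difficulty via the Modified Early Warning
Score (MEWS), runs the standard inferential comparisons, and ships a
synthetic cohort generator with known ground truth so that every stage
is testable without access to any real study data.

### Calibration statistics

Ratings are mapped to the probability scale (a table whose maximum
rating exceeds 1 is interpreted as 0–100 and divided by 100) and grouped
into confidence categories. With `n` responses, bins `j = 1..J` holding
`n_j` responses each, bin mean confidence `p̄_j`, bin proportion correct
`ē_j`, and overall proportion correct `ē`:

- **calibration score** = `(1/n) Σ_j n_j (p̄_j − ē_j)²`, 0 for perfect
  calibration, 1 for a responder who asserts confidence 1 on every
  wrong judgment and 0 on every right one;
- **over/underconfidence** = `p̄ − ē` (mean confidence minus overall
  accuracy); positive means overconfident;
- **resolution** = `(1/n) Σ_j n_j (ē_j − ē)²`, bounded above by the
  knowledge index `ē(1 − ē)`;
- **normalised resolution** = resolution / `ē(1 − ē)`, a 0–1
  discrimination measure comparable across judges.

Statistics are computed per judge (the unit of the group comparisons)
and, for hard-easy analyses, on pooled strata.

### Numerical choices

- **Bins.** Default edges `(0, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)`:
  deciles from 0.5 up, with everything below 0.5 pooled into one bottom
  bin so that `Σ n_j = n` and the `1/n` weighting is exact. Bins are
  lower-inclusive half-open; the top bin includes 1.0, so a rating of
  59 sits in [0.5, 0.6). Edges are a parameter everywhere.
- **Exact extreme cases.** Bin means of ratings are computed by summing
  the raw ratings and dividing once (`Σc / (100 n_j)` rather than
  `mean(c/100)`), so constructions such as "ten ratings of 80, eight
  correct" land exactly on the diagonal and the perfect-calibration
  score is exactly 0, not 1e-32.
- **Degenerate accuracy.** When `ē ∈ {0, 1}` the knowledge index is 0
  and discrimination is unmeasurable; normalised resolution is reported
  as 0 with a `degenerate` flag instead of 0/0. Resolution exceeding
  the knowledge index by more than 1e-9 raises an error; below that it
  is clamped to 1.
- **Empty inputs** raise; empty *bins* are retained with `n_j = 0` and
  contribute nothing.

### Calibration curves

One curve per pooled stratum (per-judge curves would rest on ~25
responses and are too sparse). The x-coordinate of a point is the bin's
mean confidence (consistent with `p̄_j`), y is the bin's proportion
correct, and ratings below a configurable minimum confidence (default
0.5) are excluded before binning, with the excluded fraction reported.
`deviation_summary` is the n-weighted mean of `x − y`, which equals the
over/underconfidence of the post-exclusion records — a useful internal
consistency check.

Note a structural caveat of binned curves: even for a perfectly
calibrated generator, a bin boundary that cuts through a stratum's
confidence distribution induces within-bin selection (x shifts, y does
not), so pointwise agreement with the identity line should only be
expected where bins do not truncate the rating distribution. The test
suite checks identity convergence with stratum-aligned edges.

### MEWS scoring and task difficulty

Five cues — systolic blood pressure (mmHg), heart rate (/min),
respiratory rate (/min), temperature (°C), consciousness (AVPU) — are
each mapped to a 0–3 subscore by a cut-off table and summed to 0–15. A
total strictly greater than the trigger threshold (default 5,
configurable) predicts "at risk". The embedded default table
(`data/mews_subbe2001.csv`) transcribes the Subbe et al. (2001)
dialect; intervals are half-open lower-inclusive, the top interval of
each cue closed at its physiological coverage limit, and any
user-supplied table in the same CSV layout can replace it. Values
outside coverage raise an error naming the cue.

Scenario difficulty is score/outcome concordance: a scenario is *easy*
when the rule's prediction matches the real patient outcome and
*difficult* when the two disagree — difficulty encodes how misleading
the vital-sign pattern is, not clinical severity.

### Inferential stage

- **Two-sample t test**: pooled-variance Student t on per-judge
  statistics, `df = n_a + n_b − 2` (95 for groups of 63 and 34).
- **Wilcoxon rank-sum**: normal approximation with midranks and the
  tie-corrected variance
  `n_a n_b /12 · [(N+1) − Σ(t³−t)/(N(N−1))]`; z is signed by the first
  group's rank sum. When every observation shares a single value the
  rank sum equals its null expectation and the test reports z = 0,
  p = 1 rather than failing.
- **Factorial ANOVA**: sequential (type I) sums of squares on the
  judge × time-pressure × difficulty table of *cell means* (not raw
  trials), with terms for time pressure (1 df), difficulty (1 df),
  participant (J − 1 df) and the time-pressure × difficulty interaction
  (1 df). With 97 judges the residual has 4·97 − 100 = 288 df; reports
  of this design sometimes print 289, which this layout cannot produce
  — the cell-mean reconstruction is an interpretation, chosen because
  it is the only layout matching the 1 and 96 numerator dfs. A term
  explaining exactly zero variance is reported as F = 0, p = 1 instead
  of a 0/0 indeterminate.
- Two-sided tests throughout, significance at p < 0.05, no multiplicity
  adjustment.

Cell means have unequal per-cell item counts (the 2×2 layout crosses an
8/17 difficulty split with a 12/13 block split), so cell-mean variances
are mildly heteroscedastic; simulation in the test suite shows the
interaction term's type-I error stays near nominal (0.05 ± 0.02 band
over 500 null cohorts).

## The synthetic cohort generator

`CohortConfig` defaults emulate the target study design: 63 students +
34 experienced judges, 25 scenarios (8 difficult, spread
deterministically across the deck so the 2×2 difficulty × pressure
layout is always populated), scenarios 1–12 time-pressured.

Generative model per record:

1. correctness ~ Bernoulli(`p_correct_easy` = 0.82 or
   `p_correct_difficult` = 0.55 by stratum; the defaults give overall
   expected accuracy (17·0.82 + 8·0.55)/25 ≈ 0.734, matching the
   emulated study's ≈73.5%);
2. the stated judgment equals the scenario's ground truth exactly when
   correct (truth drawn once per scenario with probability
   `at_risk_base_rate`, default 0.5 — the real scenario mix is
   undocumented, so this is an explicit parameter);
3. confidence ~ Normal(target, `1/self_knowledge`) truncated to [0, 1],
   ×100, rounded to an integer, where target = stratum accuracy +
   group bias + pressure shift. Default `self_knowledge` = 10 (SD 10
   points). Default group biases −0.0105 (students) and +0.0656
   (experienced) mirror the group means the emulated study reports;
   default pressure shifts ±0.03 create the confidence interaction
   (pressure raises confidence on easy items, lowers it on difficult
   ones). With `difficulty_blind_confidence=True` the target centres on
   *overall* accuracy instead, which is the textbook mechanism for the
   hard-easy effect.

With `self_knowledge` high the truncation is negligible and the
expected over/underconfidence of a group equals its bias — the
parameter-recovery tests rest on this analytic expectation.

Randomness is a hierarchical stream: `SeedSequence(seed, spawn_key=(0,))`
drives cohort-level draws and `spawn_key=(1, group, k)` drives judge `k`
of each group, so enlarging either group never changes the draws of
existing judges, and identical config + seed reproduces the table
byte-for-byte.

**What the generator does not emulate** (hence what green tests do and
do not show): no between-judge heterogeneity in skill or bias within a
group (real judges vary, so real group comparisons have more variance
than synthetic ones); no per-scenario difficulty beyond the binary
stratum; no learning, fatigue or order effects across the 25 trials; no
dependence of confidence on the particular vital-sign pattern; and no
correlation between confidence and correctness within a stratum (the
generator is bin-calibrated, not record-calibrated). Passing tests
establish that the *estimators* recover known generative parameters,
not that any empirical finding about real nurses is reproduced.

## Problem sizes used in the checked examples

Parameter recovery uses 200 judges × 200 scenarios × 20 seeds per bias
level; hard-easy emergence and type-I calibration use study-shaped
cohorts (97 × 25) with 100 and 500 replicates respectively; the power
check of the interaction term uses 4× the study's judge count over 20
replicates. These sizes make the Monte-Carlo standard errors small
relative to the tested effects while keeping the default test run
fast.

## Known limitations

- The pipeline treats the easy/difficult label as given on the record
  table; the MEWS module produces such labels from vital-sign tables
  but the generator does not synthesise vital signs.
- The ANOVA error structure is the cell-mean interpretation described
  above; a mixed-effects model on raw trials is out of scope.
- The 0–100 vs 0–1 confidence-scale auto-detection is by table maximum:
  a table whose ratings are all ≤ 1 on the 0–100 instrument would be
  misread (not an issue for data produced by this package, which always
  writes integer 0–100 ratings).
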
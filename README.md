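# robast

Risk-of-bias rubric scoring and inter-rater reliability for systematic
reviews of *in vitro* antimicrobial susceptibility testing (AST) studies.

Systematic reviewers appraising AST studies (disc diffusion, MIC methods)
need a reproducible way to record per-criterion risk-of-bias judgements,
aggregate them into domain and study-level classifications, and quantify how
well two independent reviewers agree. `robast` implements a dedicated
six-domain appraisal rubric for AST studies as a deterministic scoring
engine, with agreement statistics and traffic-light reporting on top. The
human judgement — reading a study and choosing a grade — stays with the
reviewer; the package makes everything downstream of that judgement exact
and repeatable.

## The rubric and its aggregation rules

The embedded canonical rubric has 6 bias domains and 16 criteria
(per-domain counts 2, 3, 4, 3, 3, 1):

1. Methodological bias
2. Selection bias
3. Preparation bias (incl. contamination/cross-contamination)
4. Measurement/observer bias
5. Reporting and publication bias
6. Bias related to unreported funding and conflicts of interest

Each criterion is graded on the ordinal scale **low < moderate < high**
(encoded 0/1/2). A criterion for which the study reports nothing assessable
is recorded as *not reported* and grades as **high**. Aggregation is
deterministic and fraction-exact:

- **Domain**: high if any criterion is high or strictly more than 50% of the
  domain's criteria are moderate; moderate if at least one criterion is
  moderate (none high); low only when every criterion is low. Note the
  single-criterion domain 6: one moderate criterion is a 100% moderate
  majority, so the domain grades high.
- **Overall**: the same rule one level up — high if any domain is high or
  more than 50% of domains are moderate (≥ 4 of 6 on the canonical rubric);
  low only when all six domains are low; moderate otherwise.

Two-reviewer agreement is summarized by per-study domain agreement, a pooled
3×3 confusion matrix, percent agreement, and Cohen's kappa

κ_w = 1 − Σ w_ij·o_ij / Σ w_ij·e_ij

with disagreement weights w_ij ∈ {0/1, |i−j|/2, ((i−j)/2)²} for the
unweighted, linear, and quadratic variants.

## Worked example

Simulate a ten-study, two-reviewer pilot (reviewer B copies reviewer A's
grade with probability 0.7, otherwise grades independently), score it, and
compare the reviewers:

```
$ robast simulate ratings.csv --n-studies 10 --seed 7 --copy-probability 0.7
simulated n_studies=10 marginal=(0.333333, 0.333333, 0.333334) copy_probability=0.7 seed=7

$ robast score ratings.csv --output out
study_001	reviewer_A	overall=high
study_001	reviewer_B	overall=high
...

$ robast compare ratings.csv --output out
reviewer_A vs reviewer_B (domain): agreement 88.3%, kappa=0.6452702702702702
```

`out/agreement_reviewer_A_vs_reviewer_B.json` holds the full comparison: 60
pooled study×domain grade pairs, percent agreement 0.883, and kappas 0.645
(unweighted), 0.676 (linear weights), 0.704 (quadratic weights) — the
quadratic variant penalizes low↔high flips most, so with mostly-adjacent
disagreements it is the largest of the three here. The Markdown report
renders the traffic-light table:

```
| study_id  | reviewer_id | 1  | 2  | 3  | 4  | 5  | 6  | overall |
|-----------|-------------|----|----|----|----|----|----|---------|
| study_001 | reviewer_A  | 🔴 | 🔴 | 🔴 | 🟡 | 🔴 | 🔴 | 🔴      |
| study_001 | reviewer_B  | 🟢 | 🔴 | 🔴 | 🔴 | 🔴 | 🔴 | 🔴      |
...
```

`robast init template.csv` writes a blank rating template (criterion labels
as `#` comments) for real appraisals; `robast score` accepts any long-format
CSV with columns `study_id,reviewer_id,criterion_id,grade[,note]`. Adapted
rubrics (JSON/YAML) are supported everywhere via `--rubric`; the aggregation
rules generalize the moderate-majority threshold to any domain count.

The same workflow is available as a library:

```python
from robast import canonical_rubric, read_ratings, score_assessment, corpus_reliability

rubric = canonical_rubric()
assessments = read_ratings("ratings.csv", rubric)
results = [score_assessment(a, rubric) for a in assessments]
```

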
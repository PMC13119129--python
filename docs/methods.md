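# Methods

## Scope and model

`robast` turns a human appraisal workflow into a deterministic computation.
The inputs are ordinal risk-of-bias grades (low < moderate < high, encoded
0/1/2) assigned by reviewers to the 16 criteria of a six-domain rubric for
*in vitro* antimicrobial susceptibility testing studies. Everything the
package computes — domain grades, the overall classification, agreement
statistics, reports — is a pure function of those grades. The package never
infers a grade from a study; choosing grades is explicitly out of scope.

## Aggregation rules

Both aggregation levels apply the same two-threshold rule:

- **escalate to high** when any unit is high, or when strictly more than
  half the units are moderate;
- **low** only when every unit is low;
- **moderate** otherwise (at least one moderate, none high, moderate share
  at most one half).

Thresholds are evaluated on exact integer counts (`2 * n_moderate >
n_total`), never on rounded percentages, so 2 moderate of 4 criteria is
*not* a majority while 1 of 1 is. Two consequences worth flagging:

- **Single-criterion domains.** Domain 6 (funding/conflicts) has one
  criterion; a lone moderate is a 100% moderate majority, so the domain
  grades high. This is the literal reading of the majority rule, applied
  without a lenient override so scores stay comparable across users. It is
  surfaced in the API docs because it routinely surprises first-time users.
- **Moderate-clause overlap.** Read literally, a moderate rule phrased as
  "at most half the units are moderate" would also cover the all-low case.
  The implementation resolves the three clauses in priority order — high
  rule first, then low = all-low, then moderate — the only ordering under
  which the three clauses partition all grade vectors.

The overall threshold ("at least 4 of 6 domains moderate") is implemented
as a strict majority of however many domains the governing rubric defines,
so adapted rubrics with a different domain count aggregate consistently.

The *not reported* rule — a criterion with no assessable information grades
high — is applied at ingestion: tokens `not reported` / `nr` map to
(high, flagged). A *missing row* is an error, never an implicit
"not reported": silent data loss must not change a study's classification.

Exhaustive enumeration in the test suite checks the engine against an
independently coded restatement of the rules on every per-domain grade
vector (3^n for n = 1..4) and all 3^6 domain-grade vectors, plus
monotonicity: worsening any single grade by one level never improves any
downstream grade.

## Agreement statistics

Two reviewers' assessments over a common study set are compared at a chosen
level: `domain` (default — six grade pairs per study, the unit at which
pilot validations of risk-of-bias tools usually report agreement),
`criterion` (16 pairs per study), or `overall` (one pair). All pairs pool
into a single 3×3 confusion matrix (rows reviewer A, columns reviewer B,
order low/moderate/high).

Cohen's kappa is computed in its weighted-disagreement form
κ_w = 1 − Σ w·o / Σ w·e, with o the observed proportions, e the outer
product of the marginals, and disagreement weights 0/1 (unweighted),
|i−j|/(k−1) (linear), or ((i−j)/(k−1))² (quadratic), k = 3. The unweighted
variant is exactly the 0/1-weighted case; the classical
(p_o − p_e)/(1 − p_e) form on agreement weights is algebraically identical,
and the test suite verifies both identities to 1e-12 on seeded random
matrices, plus agreement with scikit-learn's implementation as an
independent oracle.

Degenerate marginals: when the chance-expected disagreement Σ w·e is zero,
κ is 1 if observed disagreement is also zero, and otherwise reported as an
explicit undefined marker with a reason — never silently 0 or 1. For
integer tallies the undefined branch is in fact unreachable (a zero expected
disagreement forces both marginals onto the same single category, which
forces perfect agreement), but it is kept as a guard for programmatically
constructed matrices.

No confidence intervals or multi-rater statistics are computed; with more
than two reviewers the CLI emits all pairwise reports. Fractions are kept
exact internally; rendered percentages round half-up to one decimal
(4/6 → 66.7%, 5/6 → 83.3%).

## Synthetic generator

The generator emulates a two-reviewer pilot: reviewer A grades each of the
16 criteria of each study i.i.d. from a configurable marginal over
(low, moderate, high); reviewer B copies A's grade per criterion with
probability `copy_probability` and otherwise draws independently from the
same marginal. Expected per-criterion agreement has the closed form
a + (1 − a)·Σ p_i², which the tests use for parameter recovery. One seeded
`numpy` generator drives both reviewers in a fixed draw order, so identical
configurations are bit-reproducible through serialization.

Defaults: `n_studies=10` (a realistic pilot corpus), uniform marginal, and
`copy_probability=0.7`, which puts expected criterion agreement at 0.8 —
comparable to the 67–83% per-study domain agreement seen in practice for
tools of this kind. Recovery tests run at n_studies = 2,000 in the unit
suite and 10,000 in the acceptance suite (160,000 paired criterion grades),
where the binomial standard error on agreement is about 0.001; assertions
use 3 standard errors.

What the generator deliberately does not model: correlation of grades
within a domain or study (real appraisals are strongly correlated — a
sloppy study scores badly across the board), reviewer-specific severity
offsets, and per-criterion prevalence of bias in the literature. Passing
recovery tests therefore show that the statistics are computed correctly,
not that the tool's operating characteristics on real appraisals are
characterized.

## I/O and reporting choices

One fixed CSV dialect (comma-separated, UTF-8, required header
`study_id,reviewer_id,criterion_id,grade[,note]`, `#` comments) avoids
delimiter guessing; criterion ids must match the rubric exactly, and every
validation error names the offending rows or ids. Rubric documents are
JSON or YAML with the same schema either way; the canonical rubric is
embedded in the package, and criterion label text is display-only — it
never affects scoring. Reports render deterministically (byte-identical
output for identical inputs); traffic-light cells use green/yellow/red
circles with a plain `L/M/H` fallback, following the presentation
conventions of established risk-of-bias tooling. The optional figure
output is an untested thin rendering of the tested table.

## Known limitations

- The single-criterion-domain escalation (moderate → high in domain 6) is
  strict by design; users wanting leniency must adapt the rubric, not the
  engine.
- Kappa point estimates only; no uncertainty quantification.
- The synthetic model's independence assumptions (above) bound what the
  simulation-based tests can certify.
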
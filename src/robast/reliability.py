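"""Two-reviewer agreement: confusion matrices, percent agreement, Cohen's kappa.

Reviewer pairs are compared at one of three levels:

* ``domain`` — the six domain grades per study (the level at which pilot
  validations of risk-of-bias tools typically report agreement),
* ``criterion`` — the raw per-criterion grades,
* ``overall`` — one study-level grade per study.

All study-level pairs are pooled into a single 3x3 confusion matrix indexed
(low, moderate, high) for reviewer A rows and reviewer B columns.  Cohen's
kappa is computed in its weighted-disagreement form

    kappa_w = 1 - sum(w_ij * o_ij) / sum(w_ij * e_ij)

with o the observed proportions, e = outer(row, col) marginals the
chance-expected proportions, and w the disagreement weights: 0/1 (unweighted),
|i - j| / (k - 1) (linear) or ((i - j) / (k - 1))^2 (quadratic), k = 3.  When
the chance-expected disagreement is zero the statistic is 1 for perfect
agreement and otherwise undefined; the undefined case is reported as an
explicit :class:`KappaUndefined` marker, never silently coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence, Union

import numpy as np

from .rubric import Grade, RubricDef
from .scoring import Assessment, OverallResult, score_assessment

__all__ = [
    "ConfusionMatrix3",
    "KappaUndefined",
    "AgreementReport",
    "Weighting",
    "Level",
    "confusion_matrix",
    "per_study_domain_agreement",
    "cohen_kappa",
    "corpus_reliability",
    "format_percent",
]

Weighting = Literal["none", "linear", "quadratic"]
Level = Literal["domain", "criterion", "overall"]

_K = 3  # grade levels


@dataclass(frozen=True)
class KappaUndefined:
    """Marker for an undefined kappa (zero chance-expected disagreement)."""

    reason: str

    def __repr__(self) -> str:
        return f"KappaUndefined({self.reason!r})"


KappaValue = Union[float, KappaUndefined]


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 paired-grade tally: rows reviewer A, columns reviewer B.

    Index order is (low, moderate, high) on both axes.
    """

    counts: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (_K, _K):
            raise ValueError(f"confusion matrix must be 3x3, got shape {arr.shape}")
        if (arr < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)

    @property
    def n_total(self) -> int:
        return int(np.asarray(self.counts).sum())

    @property
    def n_agree(self) -> int:
        return int(np.trace(np.asarray(self.counts)))

    @property
    def percent_agreement(self) -> float:
        """Fraction of pairs on the diagonal (0-1)."""
        if self.n_total == 0:
            raise ValueError("percent agreement undefined for an empty matrix")
        return self.n_agree / self.n_total

    def transpose(self) -> "ConfusionMatrix3":
        return ConfusionMatrix3(tuple(zip(*self.counts)))


def confusion_matrix(pairs: Iterable[tuple[Grade, Grade]]) -> ConfusionMatrix3:
    """Tally paired grades into a :class:`ConfusionMatrix3`.

    Raises ``ValueError`` on empty input.
    """
    arr = np.zeros((_K, _K), dtype=int)
    n = 0
    for a, b in pairs:
        arr[int(a), int(b)] += 1
        n += 1
    if n == 0:
        raise ValueError("no grade pairs to tally")
    return ConfusionMatrix3(tuple(tuple(int(x) for x in row) for row in arr))


def _disagreement_weights(weighting: Weighting) -> np.ndarray:
    i = np.arange(_K)[:, None]
    j = np.arange(_K)[None, :]
    if weighting == "none":
        return (i != j).astype(float)
    if weighting == "linear":
        return np.abs(i - j) / (_K - 1)
    if weighting == "quadratic":
        return ((i - j) / (_K - 1)) ** 2
    raise ValueError(f"unknown weighting {weighting!r}")


def cohen_kappa(m: ConfusionMatrix3, weighting: Weighting = "none") -> KappaValue:
    """Cohen's kappa for a pooled 3x3 confusion matrix.

    ``weighting`` selects the disagreement weights: ``"none"`` (classical
    unweighted kappa), ``"linear"`` or ``"quadratic"``.  Returns a float in
    [-1, 1], or :class:`KappaUndefined` when both marginals are concentrated
    so that chance-expected disagreement is zero and agreement is imperfect.
    """
    n = m.n_total
    if n == 0:
        raise ValueError("kappa undefined for an empty matrix")
    o = m.array / n
    r = o.sum(axis=1)
    c = o.sum(axis=0)
    e = np.outer(r, c)
    w = _disagreement_weights(weighting)
    observed = float((w * o).sum())
    expected = float((w * e).sum())
    if expected == 0.0:
        if observed == 0.0:
            return 1.0
        return KappaUndefined(
            "chance-expected disagreement is zero (degenerate marginals) "
            "but observed disagreement is non-zero"
        )
    return 1.0 - observed / expected


@dataclass(frozen=True)
class StudyAgreement:
    """Per-study agreement between two reviewers at one comparison level."""

    n_match: int
    n_compared: int

    @property
    def fraction(self) -> float:
        return self.n_match / self.n_compared


def per_study_domain_agreement(a: OverallResult, b: OverallResult) -> StudyAgreement:
    """Count matching domain grades between two scored results for one study."""
    if a.study_id != b.study_id:
        raise ValueError(f"study id mismatch: {a.study_id!r} vs {b.study_id!r}")
    ga, gb = a.domain_grades(), b.domain_grades()
    if len(ga) != len(gb):
        raise ValueError(
            f"study {a.study_id!r}: reviewers scored different numbers of domains "
            f"({len(ga)} vs {len(gb)}); are they using the same rubric?"
        )
    return StudyAgreement(
        n_match=sum(x is y for x, y in zip(ga, gb)),
        n_compared=len(ga),
    )


@dataclass(frozen=True)
class AgreementReport:
    """Pooled two-reviewer comparison at one level.

    ``per_study_agreement`` maps study id to the per-study match counts;
    ``percent_agreement`` is trace(pooled_matrix) / n_total as a fraction.
    """

    level: Level
    reviewer_a: str
    reviewer_b: str
    per_study_agreement: Mapping[str, StudyAgreement]
    pooled_matrix: ConfusionMatrix3
    percent_agreement: float
    kappa_unweighted: KappaValue
    kappa_linear: KappaValue
    kappa_quadratic: KappaValue

    def kappa(self, weighting: Weighting) -> KappaValue:
        return {
            "none": self.kappa_unweighted,
            "linear": self.kappa_linear,
            "quadratic": self.kappa_quadratic,
        }[weighting]

    def to_dict(self) -> dict:
        """JSON-ready representation (undefined kappas become reason strings)."""

        def _k(v: KappaValue):
            if isinstance(v, KappaUndefined):
                return {"undefined": v.reason}
            return v

        return {
            "level": self.level,
            "reviewer_a": self.reviewer_a,
            "reviewer_b": self.reviewer_b,
            "per_study_agreement": {
                sid: {
                    "n_match": sa.n_match,
                    "n_compared": sa.n_compared,
                    "fraction": sa.fraction,
                }
                for sid, sa in self.per_study_agreement.items()
            },
            "pooled_matrix": [list(row) for row in self.pooled_matrix.counts],
            "n_pairs": self.pooled_matrix.n_total,
            "percent_agreement": self.percent_agreement,
            "kappa_unweighted": _k(self.kappa_unweighted),
            "kappa_linear": _k(self.kappa_linear),
            "kappa_quadratic": _k(self.kappa_quadratic),
        }


def format_percent(fraction: float) -> str:
    """Render a fraction as a percent with one decimal, half-up (4/6 -> '66.7%')."""
    from decimal import Decimal, ROUND_HALF_UP

    q = (Decimal(str(fraction)) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{q}%"


def _level_pairs(
    ra: OverallResult, rb: OverallResult, a: Assessment, b: Assessment, level: Level
) -> list[tuple[Grade, Grade]]:
    if level == "domain":
        return list(zip(ra.domain_grades(), rb.domain_grades()))
    if level == "criterion":
        ids = sorted(a.ratings)
        return [(a.ratings[cid].grade, b.ratings[cid].grade) for cid in ids]
    if level == "overall":
        return [(ra.grade, rb.grade)]
    raise ValueError(f"unknown comparison level {level!r}")


def corpus_reliability(
    assessments_a: Sequence[Assessment],
    assessments_b: Sequence[Assessment],
    rubric: RubricDef,
    level: Level = "domain",
) -> AgreementReport:
    """Compare two reviewers across a corpus of studies.

    Both sequences must cover the same study ids, one assessment per study per
    reviewer.  All study pairs are scored, pooled into one confusion matrix,
    and summarized by percent agreement and the three kappa variants.
    """
    by_a = {x.study_id: x for x in assessments_a}
    by_b = {x.study_id: x for x in assessments_b}
    if len(by_a) != len(assessments_a) or len(by_b) != len(assessments_b):
        raise ValueError("duplicate study ids within one reviewer's assessments")
    if set(by_a) != set(by_b):
        only_a = sorted(set(by_a) - set(by_b))
        only_b = sorted(set(by_b) - set(by_a))
        raise ValueError(
            f"study id sets differ between reviewers: only reviewer A has {only_a}, "
            f"only reviewer B has {only_b}"
        )
    if not by_a:
        raise ValueError("no assessments to compare")

    rev_a = assessments_a[0].reviewer_id
    rev_b = assessments_b[0].reviewer_id
    pooled: list[tuple[Grade, Grade]] = []
    per_study: dict[str, StudyAgreement] = {}
    for sid in sorted(by_a):
        a, b = by_a[sid], by_b[sid]
        ra = score_assessment(a, rubric)
        rb = score_assessment(b, rubric)
        pairs = _level_pairs(ra, rb, a, b, level)
        pooled.extend(pairs)
        per_study[sid] = StudyAgreement(
            n_match=sum(x is y for x, y in pairs), n_compared=len(pairs)
        )

    matrix = confusion_matrix(pooled)
    return AgreementReport(
        level=level,
        reviewer_a=rev_a,
        reviewer_b=rev_b,
        per_study_agreement=per_study,
        pooled_matrix=matrix,
        percent_agreement=matrix.percent_agreement,
        kappa_unweighted=cohen_kappa(matrix, "none"),
        kappa_linear=cohen_kappa(matrix, "linear"),
        kappa_quadratic=cohen_kappa(matrix, "quadratic"),
    )
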
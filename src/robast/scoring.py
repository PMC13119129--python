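"""Deterministic criterion → domain → overall risk-of-bias aggregation.

The aggregation rules are strict and fraction-exact:

* **Criterion**: graded low / moderate / high by the human reviewer.  A
  criterion for which the study reports no assessable information is graded
  high ("not reported" rule); the flag is preserved alongside the grade.
* **Domain**: *high* if any criterion is high or strictly more than 50% of
  the domain's criteria are moderate; *moderate* if at least one criterion
  is moderate (and none high, moderate share <= 50%); *low* only when every
  criterion is low.
* **Overall**: same shape one level up — *high* if any domain is high or
  strictly more than 50% of domains are moderate (>= 4 of 6 on the canonical
  rubric); *low* only when every domain is low; *moderate* otherwise.

Percentages are compared on exact integer counts (``2 * n_moderate >
n_total``), never on rounded floats, so 2 moderate of 4 is *not* a majority
while 1 moderate of 1 is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .rubric import DomainDef, Grade, RubricDef

__all__ = [
    "CriterionRating",
    "Assessment",
    "DomainResult",
    "OverallResult",
    "GradeTokenError",
    "CompletenessError",
    "NOT_REPORTED_TOKENS",
    "normalize_grade",
    "score_domain",
    "score_overall",
    "score_assessment",
]


class GradeTokenError(ValueError):
    """A grade token could not be interpreted."""


class CompletenessError(ValueError):
    """An assessment does not cover its rubric exactly once."""


#: Tokens recording the explicit reviewer judgement that a study reports no
#: assessable information for a criterion.  They grade as high risk.
NOT_REPORTED_TOKENS = frozenset({"not reported", "nr"})

_GRADE_TOKENS = {g.token: g for g in Grade}


def normalize_grade(token: str) -> tuple[Grade, bool]:
    """Map a free-text grade token to ``(Grade, not_reported)``.

    Matching is case- and whitespace-insensitive; underscores and hyphens
    count as spaces, so ``"Not_Reported"`` and ``"not reported"`` are
    equivalent.  "not reported" and "nr" map to ``(Grade.HIGH, True)``.
    Anything else raises :class:`GradeTokenError`.
    """
    if not isinstance(token, str) or not token.strip():
        raise GradeTokenError(f"empty or non-text grade token: {token!r}")
    norm = " ".join(token.replace("_", " ").replace("-", " ").lower().split())
    if norm in NOT_REPORTED_TOKENS:
        return Grade.HIGH, True
    try:
        return _GRADE_TOKENS[norm], False
    except KeyError:
        raise GradeTokenError(
            f"unrecognized grade token {token!r}; expected one of "
            f"low, moderate, high, not reported, nr"
        ) from None


@dataclass(frozen=True)
class CriterionRating:
    """One reviewer's grade for one criterion.

    If ``not_reported`` is true the grade must be high — enforced here so the
    invariant cannot be bypassed at construction.
    """

    criterion_id: str
    grade: Grade
    not_reported: bool = False
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.not_reported and self.grade is not Grade.HIGH:
            raise ValueError(
                f"criterion {self.criterion_id}: 'not reported' must grade as high, "
                f"got {self.grade.token}"
            )

    @classmethod
    def from_token(
        cls, criterion_id: str, token: str, note: Optional[str] = None
    ) -> "CriterionRating":
        grade, not_reported = normalize_grade(token)
        return cls(criterion_id=criterion_id, grade=grade, not_reported=not_reported, note=note)


@dataclass(frozen=True)
class Assessment:
    """One reviewer's complete set of per-criterion grades for one study."""

    study_id: str
    reviewer_id: str
    ratings: Mapping[str, CriterionRating]

    def validate_against(self, rubric: RubricDef) -> None:
        """Require exactly one rating per rubric criterion, no extras."""
        expected = set(rubric.criterion_ids)
        got = set(self.ratings)
        missing = sorted(expected - got)
        extra = sorted(got - expected)
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"missing criterion rating(s): {missing}")
            if extra:
                parts.append(f"unknown criterion id(s): {extra}")
            raise CompletenessError(
                f"study {self.study_id!r}, reviewer {self.reviewer_id!r}: " + "; ".join(parts)
            )


@dataclass(frozen=True)
class DomainResult:
    """A domain grade together with the criterion counts that justify it."""

    domain_id: int
    grade: Grade
    n_low: int
    n_moderate: int
    n_high: int

    @property
    def n_total(self) -> int:
        return self.n_low + self.n_moderate + self.n_high


@dataclass(frozen=True)
class OverallResult:
    """The full scored outcome for one study x reviewer."""

    study_id: str
    reviewer_id: str
    grade: Grade
    domain_results: tuple[DomainResult, ...]

    def domain_grades(self) -> tuple[Grade, ...]:
        return tuple(d.grade for d in self.domain_results)


def _aggregate(grades: Sequence[Grade]) -> Grade:
    """Shared majority rule: any high, or strict moderate majority -> high."""
    n = len(grades)
    n_high = sum(g is Grade.HIGH for g in grades)
    n_mod = sum(g is Grade.MODERATE for g in grades)
    if n_high >= 1 or 2 * n_mod > n:
        return Grade.HIGH
    if n_mod >= 1:
        return Grade.MODERATE
    return Grade.LOW


def score_domain(domain: DomainDef, ratings: Iterable[CriterionRating]) -> DomainResult:
    """Grade one domain from the ratings of exactly its criteria.

    Raises :class:`CompletenessError` on missing or surplus criterion ids.
    """
    by_id = {}
    for r in ratings:
        if r.criterion_id in by_id:
            raise CompletenessError(
                f"domain {domain.domain_id}: duplicate rating for {r.criterion_id!r}"
            )
        by_id[r.criterion_id] = r
    expected = set(domain.criterion_ids)
    if set(by_id) != expected:
        missing = sorted(expected - set(by_id))
        extra = sorted(set(by_id) - expected)
        raise CompletenessError(
            f"domain {domain.domain_id}: missing {missing}, surplus {extra}"
        )
    grades = [by_id[cid].grade for cid in domain.criterion_ids]
    return DomainResult(
        domain_id=domain.domain_id,
        grade=_aggregate(grades),
        n_low=sum(g is Grade.LOW for g in grades),
        n_moderate=sum(g is Grade.MODERATE for g in grades),
        n_high=sum(g is Grade.HIGH for g in grades),
    )


def score_overall(domain_results: Sequence[DomainResult]) -> Grade:
    """Combine domain grades into the study-level grade.

    The moderate-majority threshold generalizes "at least 4 of 6" to a strict
    majority of however many domains the governing rubric defines, so adapted
    rubrics score consistently.
    """
    if not domain_results:
        raise CompletenessError("no domain results to aggregate")
    return _aggregate([d.grade for d in domain_results])


def score_assessment(assessment: Assessment, rubric: RubricDef) -> OverallResult:
    """Score a complete assessment: per-domain results plus the overall grade.

    Domain results are ordered by the rubric's domain order regardless of the
    input rating order.
    """
    assessment.validate_against(rubric)
    domain_results = tuple(
        score_domain(dom, [assessment.ratings[cid] for cid in dom.criterion_ids])
        for dom in rubric.domains
    )
    return OverallResult(
        study_id=assessment.study_id,
        reviewer_id=assessment.reviewer_id,
        grade=score_overall(domain_results),
        domain_results=domain_results,
    )
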
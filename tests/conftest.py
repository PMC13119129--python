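"""Shared fixtures and the independent brute-force scoring oracle.

The oracle re-states the aggregation rules as literally as possible (exact
``Fraction`` arithmetic on grade-token lists) and stays deliberately separate
from the package implementation so the two can disagree.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Sequence

import pytest

from robast import Assessment, CriterionRating, Grade, canonical_rubric


# --- independent oracle of the aggregation rules ---------------------------


def oracle_domain_grade(tokens: Sequence[str]) -> str:
    """Literal rule: any 'high', or >50% 'moderate' -> high; any moderate ->
    moderate; all low -> low."""
    if any(t == "high" for t in tokens):
        return "high"
    if Fraction(sum(t == "moderate" for t in tokens), len(tokens)) > Fraction(1, 2):
        return "high"
    if any(t == "moderate" for t in tokens):
        return "moderate"
    return "low"


def oracle_overall_grade(domain_tokens: Sequence[str]) -> str:
    """Same shape one level up (>50% of domains moderate -> high)."""
    if any(t == "high" for t in domain_tokens):
        return "high"
    if Fraction(sum(t == "moderate" for t in domain_tokens), len(domain_tokens)) > Fraction(1, 2):
        return "high"
    if any(t == "moderate" for t in domain_tokens):
        return "moderate"
    return "low"


# --- fixtures ---------------------------------------------------------------


@pytest.fixture(scope="session")
def rubric():
    return canonical_rubric()


def make_assessment(rubric, grades, study_id="s1", reviewer_id="r1") -> Assessment:
    """Build a complete assessment.

    ``grades`` is a single Grade applied everywhere, a sequence aligned with
    ``rubric.criterion_ids``, or a mapping criterion_id -> Grade.
    """
    ids = rubric.criterion_ids
    if isinstance(grades, Grade):
        mapping = {cid: grades for cid in ids}
    elif isinstance(grades, dict):
        mapping = dict(grades)
    else:
        assert len(grades) == len(ids)
        mapping = dict(zip(ids, grades))
    return Assessment(
        study_id=study_id,
        reviewer_id=reviewer_id,
        ratings={
            cid: CriterionRating(criterion_id=cid, grade=g) for cid, g in mapping.items()
        },
    )
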
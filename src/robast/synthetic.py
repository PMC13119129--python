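"""Seeded synthetic paired-reviewer ratings for exercising the pipeline.

Emulates a two-reviewer pilot: reviewer A grades every criterion of every
study i.i.d. from a configurable marginal distribution over (low, moderate,
high); reviewer B copies A's grade with probability ``copy_probability`` and
otherwise draws independently from the same marginal.  Under this model the
expected per-criterion agreement is

    P(agree) = a + (1 - a) * sum_i p_i**2

for copy probability ``a`` and marginal ``p`` — a closed form that the test
suite uses to verify parameter recovery.  A single seeded generator drives
both reviewers, so identical (config, rubric) pairs always reproduce
identical assessments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rubric import Grade, RubricDef, canonical_rubric
from .scoring import Assessment, CriterionRating

__all__ = ["SyntheticConfig", "generate_paired_assessments", "expected_agreement"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for the paired-reviewer generator.

    marginal
        Probabilities of (low, moderate, high) for a single criterion grade.
    copy_probability
        Per-criterion probability that reviewer B copies reviewer A's grade.
    """

    n_studies: int = 10
    marginal: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    copy_probability: float = 0.7
    seed: int = 0
    reviewer_a: str = "reviewer_A"
    reviewer_b: str = "reviewer_B"

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError(f"n_studies must be positive, got {self.n_studies}")
        m = np.asarray(self.marginal, dtype=float)
        if m.shape != (3,) or (m < 0).any():
            raise ValueError(f"marginal must be 3 non-negative probabilities, got {self.marginal}")
        if abs(m.sum() - 1.0) > 1e-12:
            raise ValueError(f"marginal must sum to 1, got sum {m.sum()!r}")
        if not 0.0 <= self.copy_probability <= 1.0:
            raise ValueError(f"copy_probability must be in [0, 1], got {self.copy_probability}")


def expected_agreement(config: SyntheticConfig) -> float:
    """Closed-form per-criterion agreement probability under the model."""
    p = np.asarray(config.marginal, dtype=float)
    return config.copy_probability + (1 - config.copy_probability) * float((p**2).sum())


def generate_paired_assessments(
    config: SyntheticConfig, rubric: RubricDef | None = None
) -> tuple[list[Assessment], list[Assessment]]:
    """Generate ``n_studies`` complete assessments for each of two reviewers.

    Grades are i.i.d. across criteria and studies (no domain correlation
    structure).  Study ids are ``study_001`` ... zero-padded to a stable
    sortable width.
    """
    if rubric is None:
        rubric = canonical_rubric()
    rng = np.random.default_rng(config.seed)
    criterion_ids = rubric.criterion_ids
    n_crit = len(criterion_ids)
    width = max(3, len(str(config.n_studies)))

    # one draw block per study keeps the stream order fixed and reproducible
    assessments_a: list[Assessment] = []
    assessments_b: list[Assessment] = []
    p = np.asarray(config.marginal, dtype=float)
    for s in range(config.n_studies):
        study_id = f"study_{s + 1:0{width}d}"
        grades_a = rng.choice(3, size=n_crit, p=p)
        copy_mask = rng.random(n_crit) < config.copy_probability
        independent = rng.choice(3, size=n_crit, p=p)
        grades_b = np.where(copy_mask, grades_a, independent)
        assessments_a.append(
            Assessment(
                study_id=study_id,
                reviewer_id=config.reviewer_a,
                ratings={
                    cid: CriterionRating(criterion_id=cid, grade=Grade(int(g)))
                    for cid, g in zip(criterion_ids, grades_a)
                },
            )
        )
        assessments_b.append(
            Assessment(
                study_id=study_id,
                reviewer_id=config.reviewer_b,
                ratings={
                    cid: CriterionRating(criterion_id=cid, grade=Grade(int(g)))
                    for cid, g in zip(criterion_ids, grades_b)
                },
            )
        )
    return assessments_a, assessments_b
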
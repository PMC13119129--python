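"""Read long-format reviewer rating CSVs; write results as CSV and JSON.

The rating file dialect is deliberately fixed: comma-separated UTF-8 with a
header row and columns ``study_id, reviewer_id, criterion_id, grade`` plus an
optional ``note``.  One row per study x reviewer x criterion.  Lines starting
with ``#`` are comments (the template emitted by :func:`write_template` uses
them to carry criterion labels).  Criterion ids must match the governing
rubric exactly; unknown ids and incomplete assessments fail loudly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .reliability import AgreementReport
from .rubric import Grade, RubricDef
from .scoring import (
    Assessment,
    CompletenessError,
    CriterionRating,
    DomainResult,
    GradeTokenError,
    OverallResult,
)

__all__ = [
    "RatingsFormatError",
    "read_ratings",
    "write_ratings",
    "write_template",
    "write_results",
    "results_to_frame",
    "results_from_json",
]

REQUIRED_COLUMNS = ("study_id", "reviewer_id", "criterion_id", "grade")


class RatingsFormatError(ValueError):
    """A ratings file is structurally malformed (columns, duplicates)."""


def read_ratings(path: Union[str, Path], rubric: RubricDef) -> list[Assessment]:
    """Parse a long-format rating CSV into validated :class:`Assessment`s.

    Rows are grouped by (study_id, reviewer_id); each group must cover the
    rubric's criteria exactly once.  Grade tokens are normalized (case and
    whitespace insensitive; "not reported"/"nr" grade as high with the
    not-reported flag set).  Returned assessments are sorted by
    (study_id, reviewer_id), so row order in the file never matters.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise RatingsFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RatingsFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"expected header {', '.join(REQUIRED_COLUMNS)}[, note]"
        )
    if "note" not in df.columns:
        df = df.assign(note=None)
    df = df.reset_index(drop=True)
    # +2: header line plus 1-based numbering, for human-readable diagnostics
    df["_row"] = df.index + 2

    for col in REQUIRED_COLUMNS:
        blank = df[df[col].isna() | (df[col].str.strip() == "")]
        if len(blank):
            rows = blank["_row"].tolist()
            raise RatingsFormatError(f"{path}: empty {col!r} value in row(s) {rows}")

    dup = df.duplicated(subset=["study_id", "reviewer_id", "criterion_id"], keep=False)
    if dup.any():
        offenders = df.loc[dup]
        detail = "; ".join(
            f"({key[0]}, {key[1]}, {key[2]}) rows {sorted(grp['_row'].tolist())}"
            for key, grp in offenders.groupby(["study_id", "reviewer_id", "criterion_id"])
        )
        raise RatingsFormatError(f"{path}: duplicate (study, reviewer, criterion) rows: {detail}")

    known = set(rubric.criterion_ids)
    unknown = df[~df["criterion_id"].isin(known)]
    if len(unknown):
        ids = sorted(unknown["criterion_id"].unique())
        raise RatingsFormatError(
            f"{path}: criterion id(s) {ids} not in rubric {rubric.name!r} "
            f"(rows {unknown['_row'].tolist()})"
        )

    assessments: list[Assessment] = []
    for (study_id, reviewer_id), group in df.groupby(
        ["study_id", "reviewer_id"], sort=True
    ):
        ratings: dict[str, CriterionRating] = {}
        for rec in group.to_dict("records"):
            try:
                rating = CriterionRating.from_token(
                    criterion_id=rec["criterion_id"],
                    token=rec["grade"],
                    note=None if pd.isna(rec["note"]) else rec["note"],
                )
            except GradeTokenError as exc:
                raise GradeTokenError(f"{path}: row {rec['_row']}: {exc}") from exc
            ratings[rating.criterion_id] = rating
        assessment = Assessment(
            study_id=str(study_id), reviewer_id=str(reviewer_id), ratings=ratings
        )
        try:
            assessment.validate_against(rubric)
        except CompletenessError as exc:
            raise CompletenessError(f"{path}: {exc}") from exc
        assessments.append(assessment)
    return assessments


def write_ratings(assessments: Sequence[Assessment], path: Union[str, Path]) -> None:
    """Write assessments back out in the long-format rating CSV dialect."""
    rows = []
    for a in sorted(assessments, key=lambda x: (x.study_id, x.reviewer_id)):
        for cid in sorted(a.ratings):
            r = a.ratings[cid]
            token = "not reported" if r.not_reported else r.grade.token
            rows.append(
                {
                    "study_id": a.study_id,
                    "reviewer_id": a.reviewer_id,
                    "criterion_id": cid,
                    "grade": token,
                    "note": r.note if r.note is not None else "",
                }
            )
    pd.DataFrame(rows, columns=[*REQUIRED_COLUMNS, "note"]).to_csv(path, index=False)


def write_template(
    path: Union[str, Path],
    rubric: RubricDef,
    study_id: str = "STUDY_ID",
    reviewer_id: str = "REVIEWER_ID",
) -> None:
    """Write a blank rating template for one study/reviewer stub.

    Criterion labels are carried as ``#`` comment lines so the file documents
    itself; the grade column is left empty for the reviewer to fill in with
    low / moderate / high / not reported.
    """
    lines = [",".join([*REQUIRED_COLUMNS, "note"])]
    for dom in rubric.domains:
        lines.append(f"# Domain {dom.domain_id}: {dom.name}")
        for c in dom.criteria:
            lines.append(f"# {c.id}: {c.label}")
            lines.append(f"{study_id},{reviewer_id},{c.id},,")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --- results output ---------------------------------------------------------


def results_to_frame(results: Sequence[OverallResult]) -> pd.DataFrame:
    """Flatten results to one row per study x reviewer x domain plus overall."""
    rows = []
    for res in results:
        for d in res.domain_results:
            rows.append(
                {
                    "study_id": res.study_id,
                    "reviewer_id": res.reviewer_id,
                    "domain": str(d.domain_id),
                    "grade": d.grade.token,
                    "n_low": d.n_low,
                    "n_moderate": d.n_moderate,
                    "n_high": d.n_high,
                }
            )
        rows.append(
            {
                "study_id": res.study_id,
                "reviewer_id": res.reviewer_id,
                "domain": "overall",
                "grade": res.grade.token,
                "n_low": None,
                "n_moderate": None,
                "n_high": None,
            }
        )
    return pd.DataFrame(rows)


def _result_to_dict(res: OverallResult) -> dict:
    return {
        "study_id": res.study_id,
        "reviewer_id": res.reviewer_id,
        "grade": res.grade.token,
        "domains": [
            {
                "domain_id": d.domain_id,
                "grade": d.grade.token,
                "n_low": d.n_low,
                "n_moderate": d.n_moderate,
                "n_high": d.n_high,
            }
            for d in res.domain_results
        ],
    }


def write_results(
    results: Sequence[OverallResult],
    destination: Union[str, Path],
    report: Optional[AgreementReport] = None,
    stem: str = "results",
) -> dict[str, Path]:
    """Write scored results (and optionally an agreement report) to a directory.

    Emits ``<stem>.csv`` (one row per study x reviewer x domain plus an
    overall row) and ``<stem>.json`` (the full data model); with ``report``,
    also ``agreement.json``.  Returns the paths written, keyed by format.
    """
    if not results:
        raise ValueError("no results to write")
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    csv_path = destination / f"{stem}.csv"
    json_path = destination / f"{stem}.json"
    results_to_frame(results).to_csv(csv_path, index=False)
    doc: dict = {"results": [_result_to_dict(r) for r in results]}
    if report is not None:
        doc["agreement"] = report.to_dict()
    json_path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    written = {"csv": csv_path, "json": json_path}
    if report is not None:
        agreement_path = destination / "agreement.json"
        agreement_path.write_text(
            json.dumps(report.to_dict(), indent=2) + "\n", encoding="utf-8"
        )
        written["agreement"] = agreement_path
    return written


def results_from_json(path: Union[str, Path]) -> list[OverallResult]:
    """Parse the JSON document written by :func:`write_results` back to results."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for r in doc["results"]:
        domains = tuple(
            DomainResult(
                domain_id=d["domain_id"],
                grade=Grade[d["grade"].upper()],
                n_low=d["n_low"],
                n_moderate=d["n_moderate"],
                n_high=d["n_high"],
            )
            for d in r["domains"]
        )
        out.append(
            OverallResult(
                study_id=r["study_id"],
                reviewer_id=r["reviewer_id"],
                grade=Grade[r["grade"].upper()],
                domain_results=domains,
            )
        )
    return out
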
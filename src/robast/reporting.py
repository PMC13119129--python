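"""Traffic-light tables and corpus summaries — the presentation surface.

Risk-of-bias tools are conventionally presented as a traffic-light table:
studies as rows, bias domains as columns plus an overall column, cells
color-coded low (green) / moderate (yellow) / high (red).  Rendering is a
pure function of the scored results, so identical inputs always produce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import pandas as pd

from .reliability import AgreementReport, KappaUndefined, format_percent
from .rubric import Grade
from .scoring import OverallResult

__all__ = [
    "TrafficLightTable",
    "traffic_light",
    "summary_counts",
    "render_markdown_report",
    "traffic_light_figure",
]

GLYPHS = {Grade.LOW: "\U0001f7e2", Grade.MODERATE: "\U0001f7e1", Grade.HIGH: "\U0001f534"}
LETTERS = {Grade.LOW: "L", Grade.MODERATE: "M", Grade.HIGH: "H"}


@dataclass(frozen=True)
class TrafficLightTable:
    """One row per study x reviewer; columns are domain ids plus 'overall'."""

    domain_ids: tuple[int, ...]
    rows: tuple[tuple[str, str, tuple[Grade, ...]], ...]  # (study, reviewer, grades)

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(str(d) for d in self.domain_ids) + ("overall",)

    def to_frame(self, glyphs: bool = False) -> pd.DataFrame:
        mapping = GLYPHS if glyphs else LETTERS
        data = [
            {
                "study_id": s,
                "reviewer_id": r,
                **{col: mapping[g] for col, g in zip(self.column_names, grades)},
            }
            for s, r, grades in self.rows
        ]
        return pd.DataFrame(data)

    def to_markdown(self, glyphs: bool = True) -> str:
        df = self.to_frame(glyphs=glyphs)
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
        body = ["| " + " | ".join(str(v) for v in rec) + " |" for rec in df.itertuples(index=False)]
        return "\n".join([header, sep, *body])


def traffic_light(results: Sequence[OverallResult]) -> TrafficLightTable:
    """Arrange scored results into a traffic-light table.

    Rows are ordered by (study_id, reviewer_id).  All results must share one
    rubric structure (same domain id sequence).
    """
    if not results:
        raise ValueError("no results to tabulate")
    domain_ids = tuple(d.domain_id for d in results[0].domain_results)
    rows = []
    for res in sorted(results, key=lambda r: (r.study_id, r.reviewer_id)):
        ids = tuple(d.domain_id for d in res.domain_results)
        if ids != domain_ids:
            raise ValueError(
                f"mixed rubrics: study {res.study_id!r} has domains {ids}, "
                f"expected {domain_ids}"
            )
        rows.append(
            (res.study_id, res.reviewer_id, (*res.domain_grades(), res.grade))
        )
    return TrafficLightTable(domain_ids=domain_ids, rows=tuple(rows))


def summary_counts(results: Sequence[OverallResult]) -> pd.DataFrame:
    """Grade distribution per domain and overall across results.

    Returns a frame indexed by domain label ('1'..'6', 'overall') with count
    and fraction columns; fractions sum to 1 within each row.
    """
    if not results:
        raise ValueError("no results to summarize")
    table = traffic_light(results)
    records = []
    n = len(table.rows)
    for j, col in enumerate(table.column_names):
        grades = [row[2][j] for row in table.rows]
        counts = {g: sum(x is g for x in grades) for g in Grade}
        records.append(
            {
                "domain": col,
                "n_low": counts[Grade.LOW],
                "n_moderate": counts[Grade.MODERATE],
                "n_high": counts[Grade.HIGH],
                "frac_low": counts[Grade.LOW] / n,
                "frac_moderate": counts[Grade.MODERATE] / n,
                "frac_high": counts[Grade.HIGH] / n,
            }
        )
    return pd.DataFrame(records).set_index("domain")


def _render_kappa(v: Union[float, KappaUndefined]) -> str:
    if isinstance(v, KappaUndefined):
        return f"undefined ({v.reason})"
    return f"{v:.3f}"


def render_markdown_report(
    results: Sequence[OverallResult],
    report: AgreementReport = None,
    glyphs: bool = True,
    title: str = "Risk-of-bias assessment report",
) -> str:
    """Assemble the full Markdown report: traffic lights, summary, agreement."""
    table = traffic_light(results)
    summary = summary_counts(results)
    lines = [f"# {title}", "", "## Traffic-light table", ""]
    legend = (
        "Legend: \U0001f7e2 low / \U0001f7e1 moderate / \U0001f534 high risk of bias"
        if glyphs
        else "Legend: L low / M moderate / H high risk of bias"
    )
    lines += [legend, "", table.to_markdown(glyphs=glyphs), "", "## Grade distribution", ""]
    dist = summary.reset_index()
    header = "| domain | low | moderate | high |"
    sep = "|---|---|---|---|"
    body = [
        f"| {r.domain} | {r.n_low} ({format_percent(r.frac_low)}) "
        f"| {r.n_moderate} ({format_percent(r.frac_moderate)}) "
        f"| {r.n_high} ({format_percent(r.frac_high)}) |"
        for r in dist.itertuples(index=False)
    ]
    lines += [header, sep, *body]
    if report is not None:
        lines += [
            "",
            f"## Inter-reviewer agreement ({report.level} level)",
            "",
            f"Reviewers compared: {report.reviewer_a} vs {report.reviewer_b} "
            f"over {report.pooled_matrix.n_total} pooled grade pairs.",
            "",
            f"- Percent agreement: {format_percent(report.percent_agreement)}",
            f"- Cohen's kappa (unweighted): {_render_kappa(report.kappa_unweighted)}",
            f"- Cohen's kappa (linear weights): {_render_kappa(report.kappa_linear)}",
            f"- Cohen's kappa (quadratic weights): {_render_kappa(report.kappa_quadratic)}",
            "",
            "Per-study agreement:",
            "",
            "| study | matched | compared | agreement |",
            "|---|---|---|---|",
        ]
        for sid in sorted(report.per_study_agreement):
            sa = report.per_study_agreement[sid]
            lines.append(
                f"| {sid} | {sa.n_match} | {sa.n_compared} | {format_percent(sa.fraction)} |"
            )
    return "\n".join(lines) + "\n"


def traffic_light_figure(results: Sequence[OverallResult], path) -> None:
    """Render the traffic-light table as a figure (requires matplotlib).

    A thin visual wrapper over :func:`traffic_light`; only the underlying
    table carries tested semantics.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    table = traffic_light(results)
    colors = {Grade.LOW: "#2ca02c", Grade.MODERATE: "#ffbf00", Grade.HIGH: "#d62728"}
    n_rows = len(table.rows)
    n_cols = len(table.column_names)
    fig, ax = plt.subplots(figsize=(1.0 * n_cols + 3, 0.45 * n_rows + 1.2))
    for i, (study, reviewer, grades) in enumerate(table.rows):
        y = n_rows - 1 - i
        ax.text(-0.7, y, f"{study} / {reviewer}", ha="right", va="center", fontsize=8)
        for j, g in enumerate(grades):
            ax.add_patch(Circle((j, y), 0.32, color=colors[g]))
    for j, name in enumerate(table.column_names):
        ax.text(j, n_rows - 0.3, name, ha="center", va="bottom", fontsize=8)
    ax.set_xlim(-4, n_cols)
    ax.set_ylim(-0.7, n_rows + 0.5)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
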
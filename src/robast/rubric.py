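"""Rubric data model and the canonical AST risk-of-bias rubric.

A rubric is an ordered collection of bias *domains*, each holding an ordered
list of appraisable *criteria*.  Every criterion is graded on a three-level
ordinal scale (low < moderate < high risk of bias).  The canonical rubric for
in vitro antimicrobial susceptibility testing (AST) studies — six domains,
sixteen criteria — ships embedded in this module; adapted rubrics can be
loaded from JSON or YAML documents with the same schema.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Union

import yaml

__all__ = [
    "Grade",
    "CriterionDef",
    "DomainDef",
    "RubricDef",
    "RubricError",
    "canonical_rubric",
    "load_rubric",
    "dump_rubric",
]


class Grade(enum.IntEnum):
    """Ordinal risk-of-bias grade: low < moderate < high.

    Integer values (0, 1, 2) are the fixed encoding used for ordinal
    disagreement weights in reliability statistics.
    """

    LOW = 0
    MODERATE = 1
    HIGH = 2

    @property
    def token(self) -> str:
        """Lower-case text token ('low', 'moderate', 'high')."""
        return self.name.lower()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.token


class RubricError(ValueError):
    """A rubric document is malformed or violates a structural invariant."""


@dataclass(frozen=True)
class CriterionDef:
    """One appraisable item within a domain.

    ``id`` is the dotted identifier as printed in the rubric (e.g. ``"3.2"``);
    it is a string, never a float, so ids like ``"3.10"`` survive round-trips.
    The integer prefix of ``id`` must equal ``domain_id``.
    """

    id: str
    domain_id: int
    label: str

    def __post_init__(self) -> None:
        prefix, _, rest = self.id.partition(".")
        if not (prefix.isdigit() and rest):
            raise RubricError(f"criterion id {self.id!r} is not of the form '<domain>.<n>'")
        if int(prefix) != self.domain_id:
            raise RubricError(
                f"criterion id {self.id!r} does not belong to domain {self.domain_id}"
            )


@dataclass(frozen=True)
class DomainDef:
    """A named bias domain with a non-empty ordered list of criteria."""

    domain_id: int
    name: str
    criteria: tuple[CriterionDef, ...]

    def __post_init__(self) -> None:
        if not self.criteria:
            raise RubricError(f"domain {self.domain_id} ({self.name!r}) has no criteria")
        for c in self.criteria:
            if c.domain_id != self.domain_id:
                raise RubricError(
                    f"criterion {c.id!r} listed under domain {self.domain_id}"
                )

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)


@dataclass(frozen=True)
class RubricDef:
    """A complete rubric: ordered domains, unique criterion ids throughout."""

    name: str
    version: str
    domains: tuple[DomainDef, ...]
    _index: dict[str, CriterionDef] = field(
        init=False, repr=False, compare=False, hash=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        if not self.domains:
            raise RubricError("rubric has no domains")
        seen: dict[str, int] = {}
        for dom in self.domains:
            for c in dom.criteria:
                if c.id in seen:
                    raise RubricError(
                        f"duplicate criterion id {c.id!r} (domains {seen[c.id]} and {dom.domain_id})"
                    )
                seen[c.id] = dom.domain_id
                self._index[c.id] = c
        ids = [d.domain_id for d in self.domains]
        if len(set(ids)) != len(ids):
            raise RubricError(f"duplicate domain ids: {ids}")

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_criteria(self) -> int:
        return sum(len(d.criteria) for d in self.domains)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        """All criterion ids in rubric order."""
        return tuple(c.id for d in self.domains for c in d.criteria)

    def criterion(self, criterion_id: str) -> CriterionDef:
        try:
            return self._index[criterion_id]
        except KeyError:
            raise KeyError(f"criterion {criterion_id!r} not in rubric {self.name!r}") from None

    def domain(self, domain_id: int) -> DomainDef:
        for d in self.domains:
            if d.domain_id == domain_id:
                return d
        raise KeyError(f"domain {domain_id} not in rubric {self.name!r}")

    def __iter__(self) -> Iterator[DomainDef]:
        return iter(self.domains)


# --- canonical rubric -------------------------------------------------------

_CANONICAL_SPEC: list[tuple[int, str, list[tuple[str, str]]]] = [
    (
        1,
        "Methodological Bias",
        [
            (
                "1.1",
                "Detailed description of the study protocol and adherence to a "
                "standardized methodology based on the EUCAST and/or CLSI guidelines "
                "for the standard operating procedures for every step",
            ),
            (
                "1.2",
                "Use of appropriate statistical models and analyses for the type of "
                "data (with justification, if applicable)",
            ),
        ],
    ),
    (
        2,
        "Selection Bias",
        [
            (
                "2.1",
                "Explicitly stated strain inclusion and exclusion criteria and "
                "selection methods (random or consecutive selection process, or based "
                "on availability/convenience/focused with justification)",
            ),
            (
                "2.2",
                "Clearly defined and described bacterial strains (e.g., species, "
                "source, clinical relevance)",
            ),
            (
                "2.3",
                "Number and diversity of isolates (clinical sites, resistance "
                "profiles, sample types) adequate and representative of real-world "
                "settings - or justification provided (if applicable)",
            ),
        ],
    ),
    (
        3,
        "Preparation Bias (including contamination/cross-contamination bias)",
        [
            (
                "3.1",
                "Confirmed purity of isolates and antimicrobials before testing and "
                "description of methods used for confirmation",
            ),
            (
                "3.2",
                "Detailed description of inoculum preparation, standardization, "
                "inoculation, and incubation",
            ),
            (
                "3.3",
                "Use of proper solvents and description of dilution methods, detailed "
                "preparation, standardization, and storage of stocks",
            ),
            (
                "3.4",
                "Report on the implementation of aseptic techniques, use of sterile "
                "media and equipment, and contamination control measures - use of "
                "positive and negative controls and reference strains for validation",
            ),
        ],
    ),
    (
        4,
        "Measurement/Observer Bias",
        [
            (
                "4.1",
                "Independent read of results by two or more observers or blinded "
                "reviewers, and results blinded to strain identity and drug tested",
            ),
            (
                "4.2",
                "Use of calibrated and validated equipment for the conduction of "
                "measurements",
            ),
            (
                "4.3",
                "Reported repeat of tests (replicates) with complete documentation "
                "of results",
            ),
        ],
    ),
    (
        5,
        "Reporting and Publication Bias",
        [
            (
                "5.1",
                "Report on all outcomes and relevant data (including negative "
                "results), and deviations - no apparent selective reporting (e.g., "
                "omission of failed assays) - justification of missing or excluded "
                "data (if applicable)",
            ),
            (
                "5.2",
                "Presentation of raw MIC/MBC or report on other relevant data, or "
                "availability of supplementary material (raw data in appendices or "
                "on open repositories)",
            ),
            (
                "5.3",
                "Standard interpretive criteria (e.g., CLSI/EUCAST breakpoints) used "
                "and referenced",
            ),
        ],
    ),
    (
        6,
        "Bias related to unreported funding and conflicts of interest",
        [
            ("6.1", "Clearly disclosed funding and conflicts of interest"),
        ],
    ),
]


def canonical_rubric() -> RubricDef:
    """The embedded risk-of-bias rubric for in vitro AST studies.

    Six domains (methodological, selection, preparation/contamination,
    measurement/observer, reporting/publication, funding/conflicts) holding
    sixteen criteria with per-domain counts (2, 3, 4, 3, 3, 1).  Repeated
    calls return structurally identical, immutable values.
    """
    return RubricDef(
        name="RoB Assessment Tool for In vitro Antimicrobial Susceptibility Studies",
        version="1.0",
        domains=tuple(
            DomainDef(
                domain_id=did,
                name=name,
                criteria=tuple(
                    CriterionDef(id=cid, domain_id=did, label=label)
                    for cid, label in crits
                ),
            )
            for did, name, crits in _CANONICAL_SPEC
        ),
    )


# --- serialization ----------------------------------------------------------


def _rubric_to_dict(rubric: RubricDef) -> dict[str, Any]:
    return {
        "name": rubric.name,
        "version": rubric.version,
        "domains": [
            {
                "domain_id": d.domain_id,
                "name": d.name,
                "criteria": [{"id": c.id, "label": c.label} for c in d.criteria],
            }
            for d in rubric.domains
        ],
    }


def dump_rubric(rubric: RubricDef, path: Union[str, Path]) -> None:
    """Serialize a rubric to JSON or YAML, chosen by file extension."""
    path = Path(path)
    doc = _rubric_to_dict(rubric)
    if path.suffix.lower() in {".yaml", ".yml"}:
        text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
    else:
        text = json.dumps(doc, indent=2, ensure_ascii=False) + "\n"
    path.write_text(text, encoding="utf-8")


def _rubric_from_dict(doc: Any, source: str) -> RubricDef:
    if not isinstance(doc, dict):
        raise RubricError(f"{source}: rubric document must be a mapping, got {type(doc).__name__}")
    missing = {"name", "version", "domains"} - doc.keys()
    if missing:
        raise RubricError(f"{source}: missing top-level field(s) {sorted(missing)}")
    domains = doc["domains"]
    if not isinstance(domains, list):
        raise RubricError(f"{source}: 'domains' must be a list")
    built: list[DomainDef] = []
    for i, d in enumerate(domains):
        if not isinstance(d, dict) or not {"domain_id", "name", "criteria"} <= d.keys():
            raise RubricError(
                f"{source}: domain entry {i} must be a mapping with "
                "'domain_id', 'name', 'criteria'"
            )
        crits = []
        for j, c in enumerate(d["criteria"]):
            if not isinstance(c, dict) or not {"id", "label"} <= c.keys():
                raise RubricError(
                    f"{source}: criterion entry {j} of domain {d['domain_id']} must "
                    "be a mapping with 'id' and 'label'"
                )
            crits.append(
                CriterionDef(id=str(c["id"]), domain_id=int(d["domain_id"]), label=str(c["label"]))
            )
        built.append(
            DomainDef(domain_id=int(d["domain_id"]), name=str(d["name"]), criteria=tuple(crits))
        )
    return RubricDef(name=str(doc["name"]), version=str(doc["version"]), domains=tuple(built))


def load_rubric(path: Union[str, Path]) -> RubricDef:
    """Load and validate a rubric document (JSON or YAML, UTF-8).

    Loading the serialized canonical rubric yields a value equal to
    :func:`canonical_rubric`.  Structural violations (duplicate or mismatched
    criterion ids, empty domains, missing fields) raise :class:`RubricError`
    naming the offending field.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in {".yaml", ".yml"}:
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise RubricError(f"{path}: YAML parse failure: {exc}") from exc
    else:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise RubricError(f"{path}: JSON parse failure at line {exc.lineno}: {exc.msg}") from exc
    return _rubric_from_dict(doc, source=str(path))
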
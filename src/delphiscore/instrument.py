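"""Checklist scoring instruments for care-burden assessment.

A scoring instrument is a set of *categories*, each worth a fixed number of
points, and a set of *problems*, each belonging to exactly one category.  A
patient assessment is the set of problems the patient currently presents
with; the patient's score is the sum of the points of every category with at
least one present problem.  A category contributes its points once no matter
how many of its problems are present, so the maximum attainable score is the
sum of all category points.

The bundled default is a seven-category nursing score for home palliative
care (parenteral access, tubes, simple and complex wound care, hygiene,
delirium, social/family issues) whose category points sum to 16.  Points are
:class:`decimal.Decimal` throughout — half-point categories (2.5) are part
of the instrument and must render exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import ConfigError, UnknownProblemError

__all__ = [
    "Problem",
    "Category",
    "Instrument",
    "PatientAssessment",
    "load_instrument",
    "default_instrument",
    "score_patient",
    "max_score",
    "read_assessments",
]


@dataclass(frozen=True)
class Problem:
    """A concrete care need (e.g. a urinary catheter) triggering a category."""

    id: str
    label: str
    category_id: str


@dataclass(frozen=True)
class Category:
    """A group of related problems worth a fixed point value."""

    id: str
    label: str
    points: Decimal

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ConfigError(
                f"category {self.id!r}: points must be >= 0, got {self.points}"
            )


@dataclass(frozen=True)
class Instrument:
    """An ordered collection of categories and their member problems."""

    name: str
    categories: tuple[Category, ...]
    problems: tuple[Problem, ...]
    _problem_index: Mapping[str, Problem] = field(
        init=False, repr=False, compare=False, default=None
    )

    def __post_init__(self) -> None:
        cat_ids = [c.id for c in self.categories]
        if len(set(cat_ids)) != len(cat_ids):
            dupes = sorted({c for c in cat_ids if cat_ids.count(c) > 1})
            raise ConfigError(f"duplicate category id(s): {', '.join(dupes)}")
        prob_ids = [p.id for p in self.problems]
        if len(set(prob_ids)) != len(prob_ids):
            dupes = sorted({p for p in prob_ids if prob_ids.count(p) > 1})
            raise ConfigError(f"duplicate problem id(s): {', '.join(dupes)}")
        known = set(cat_ids)
        for p in self.problems:
            if p.category_id not in known:
                raise ConfigError(
                    f"problem {p.id!r} references unknown category "
                    f"{p.category_id!r}"
                )
        object.__setattr__(
            self, "_problem_index", {p.id: p for p in self.problems}
        )

    @property
    def problem_ids(self) -> frozenset[str]:
        return frozenset(self._problem_index)

    def category(self, category_id: str) -> Category:
        for c in self.categories:
            if c.id == category_id:
                return c
        raise KeyError(category_id)

    def problems_in(self, category_id: str) -> tuple[Problem, ...]:
        return tuple(
            p for p in self.problems if p.category_id == category_id
        )


@dataclass(frozen=True)
class PatientAssessment:
    """The set of instrument problems a patient currently presents with."""

    patient_id: str
    present_problems: frozenset[str]

    def __init__(self, patient_id: str, present_problems: Iterable[str]):
        object.__setattr__(self, "patient_id", patient_id)
        object.__setattr__(
            self, "present_problems", frozenset(present_problems)
        )


def _parse_points(raw, where: str) -> Decimal:
    # str() round-trip keeps JSON/YAML floats like 2.5 exact
    try:
        return Decimal(str(raw))
    except (InvalidOperation, TypeError) as exc:
        raise ConfigError(f"{where}: points value {raw!r} is not numeric") from exc


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"{where}: missing required field {key!r}")
    return mapping[key]


def load_instrument(source: str | Path | Mapping) -> Instrument:
    """Build a validated :class:`Instrument` from a config document.

    ``source`` may be a mapping already parsed, or a path to a JSON or YAML
    file with keys ``name``, ``categories`` (id, label, points) and
    ``problems`` (id, label, category_id).  Referential integrity, id
    uniqueness and point non-negativity are enforced; violations raise
    :class:`~delphiscore.errors.ConfigError` naming the offending field.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in {".yaml", ".yml"}:
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    else:
        doc = source
    if not isinstance(doc, Mapping):
        raise ConfigError("instrument config must be a mapping")

    name = doc.get("name", "unnamed instrument")
    categories = []
    for i, raw in enumerate(_require(doc, "categories", "instrument")):
        where = f"categories[{i}]"
        categories.append(
            Category(
                id=str(_require(raw, "id", where)),
                label=str(raw.get("label", raw["id"])),
                points=_parse_points(_require(raw, "points", where), where),
            )
        )
    problems = []
    for i, raw in enumerate(_require(doc, "problems", "instrument")):
        where = f"problems[{i}]"
        problems.append(
            Problem(
                id=str(_require(raw, "id", where)),
                label=str(raw.get("label", raw["id"])),
                category_id=str(_require(raw, "category_id", where)),
            )
        )
    return Instrument(
        name=str(name), categories=tuple(categories), problems=tuple(problems)
    )


def default_instrument() -> Instrument:
    """The bundled seven-category nursing score (maximum 16 points)."""
    with resources.files("delphiscore.data").joinpath(
        "nursing_score.json"
    ).open("r", encoding="utf-8") as fh:
        return load_instrument(json.load(fh))


def max_score(instrument: Instrument) -> Decimal:
    """Sum of all category points — the score of a patient with every problem."""
    return sum((c.points for c in instrument.categories), Decimal(0))


def score_patient(
    assessment: PatientAssessment, instrument: Instrument
) -> Decimal:
    """Score an assessment: each category with >= 1 present problem adds its
    points exactly once.

    Unknown problem ids raise :class:`~delphiscore.errors.UnknownProblemError`
    listing every offending id — a silent skip would understate care burden.
    """
    unknown = assessment.present_problems - instrument.problem_ids
    if unknown:
        raise UnknownProblemError(unknown)
    triggered = {
        instrument._problem_index[pid].category_id
        for pid in assessment.present_problems
    }
    return sum(
        (c.points for c in instrument.categories if c.id in triggered),
        Decimal(0),
    )


def read_assessments(source: str | Path) -> list[PatientAssessment]:
    """Read patient checklists from long-format CSV (patient_id, problem_id)
    or from a JSON document mapping patient ids to problem-id lists."""
    path = Path(source)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        return [
            PatientAssessment(str(pid), [str(p) for p in probs])
            for pid, probs in doc.items()
        ]
    frame = pd.read_csv(path, dtype=str)
    required = {"patient_id", "problem_id"}
    if not required.issubset(frame.columns):
        raise ConfigError(
            "assessment CSV needs columns patient_id, problem_id; got "
            + ", ".join(frame.columns)
        )
    out = []
    for pid, group in frame.groupby("patient_id", sort=True):
        out.append(
            PatientAssessment(str(pid), group["problem_id"].dropna().tolist())
        )
    return out
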
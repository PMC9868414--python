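"""Drug-name normalization and composite adverse-event definitions.

Spontaneous reports carry verbatim drug strings — brand names, generic
names, abbreviations, dose-qualified variants — which must be mapped to
a canonical drugname before counting.  The mapping here is an exact
lookup after case-folding and whitespace normalization: no fuzzy or
substring matching, because approximate matching silently inflates
signal counts.  Compound preparations (fixed-dose combinations such as
losartan + hydrochlorothiazide products) are canonical names in their
own right, distinct from their component drugs.

Adverse events are defined as named sets of MedDRA Preferred Terms
(PTs); a report "has" an event when any of its reaction PTs belongs to
the event's PT set (case-insensitive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from pharmsig.models import ReportRecord, ValidationError

PathLike = Union[str, Path]


class Unmapped:
    """Sentinel for a verbatim drug name with no vocabulary match."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNMAPPED"

    def __bool__(self) -> bool:
        return False


UNMAPPED = Unmapped()


def normalize_name(name: str) -> str:
    """Case-fold and collapse internal whitespace for dictionary lookup."""
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class VocabularyEntry:
    canonical: str
    drug_class: str
    synonyms: tuple[str, ...] = ()


@dataclass
class DrugVocabulary:
    """Canonical drugnames with classes and resolvable synonyms.

    The canonical name is implicitly a synonym of itself.  After
    normalization no synonym may resolve to two canonical names.
    """

    entries: list[VocabularyEntry]
    _index: dict[str, str] = field(init=False, repr=False)
    _classes: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, str] = {}
        classes: dict[str, str] = {}
        for entry in self.entries:
            if not entry.canonical or not entry.canonical.strip():
                raise ValidationError("vocabulary entry with empty canonical name")
            if not entry.drug_class or not entry.drug_class.strip():
                raise ValidationError(
                    f"vocabulary entry {entry.canonical!r} has no drug class"
                )
            if entry.canonical in classes:
                raise ValidationError(
                    f"duplicate canonical name {entry.canonical!r}"
                )
            classes[entry.canonical] = entry.drug_class
            for name in (entry.canonical, *entry.synonyms):
                key = normalize_name(name)
                if not key:
                    raise ValidationError(
                        f"empty synonym under canonical {entry.canonical!r}"
                    )
                owner = index.get(key)
                if owner is not None and owner != entry.canonical:
                    raise ValidationError(
                        f"synonym {name!r} maps to both {owner!r} and {entry.canonical!r}"
                    )
                index[key] = entry.canonical
        self._index = index
        self._classes = classes

    @property
    def canonical_names(self) -> list[str]:
        """Canonical names in vocabulary (input) order."""
        return [e.canonical for e in self.entries]

    def drug_class_of(self, canonical: str) -> str:
        try:
            return self._classes[canonical]
        except KeyError:
            raise KeyError(f"unknown canonical drug name {canonical!r}") from None

    def __contains__(self, canonical: str) -> bool:
        return canonical in self._classes

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EventDefinition:
    """A named adverse event composed of one or more Preferred Terms."""

    label: str
    pts: frozenset[str]

    def __init__(self, label: str, pts: Iterable[str]):
        norm = frozenset(normalize_name(pt) for pt in pts)
        if not norm or any(not pt for pt in norm):
            raise ValidationError(f"event {label!r} needs a non-empty PT set")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "pts", norm)


def load_vocabulary(path: PathLike) -> DrugVocabulary:
    """Load a drug vocabulary from a YAML file.

    Schema: a list of mappings with keys ``canonical`` (string),
    ``class`` (string) and optional ``synonyms`` (list of strings).
    Synonym collisions and missing classes raise
    :class:`~pharmsig.models.ValidationError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        raise ValidationError(f"vocabulary file {path} is empty")
    if not isinstance(raw, list):
        raise ValidationError("vocabulary file must contain a list of entries")
    entries = []
    for item in raw:
        if "canonical" not in item:
            raise ValidationError(f"vocabulary entry without 'canonical': {item!r}")
        if "class" not in item or item["class"] in (None, ""):
            raise ValidationError(
                f"vocabulary entry {item.get('canonical')!r} is missing 'class'"
            )
        entries.append(
            VocabularyEntry(
                canonical=str(item["canonical"]),
                drug_class=str(item["class"]),
                synonyms=tuple(str(s) for s in item.get("synonyms") or ()),
            )
        )
    return DrugVocabulary(entries=entries)


def load_events(path: PathLike) -> list[EventDefinition]:
    """Load event definitions from YAML: mapping of label -> list of PTs."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not raw or not isinstance(raw, dict):
        raise ValidationError(f"event file {path} must map labels to PT lists")
    return [EventDefinition(label, pts) for label, pts in raw.items()]


def map_drug_name(vocab: DrugVocabulary, verbatim: str):
    """Resolve a verbatim drug mention to its canonical name.

    Exact match after normalization; returns :data:`UNMAPPED` when the
    string is not in the vocabulary (never a guess).
    """
    return vocab._index.get(normalize_name(verbatim), UNMAPPED)


def report_has_drug(vocab: DrugVocabulary, report: ReportRecord, canonical_name: str) -> bool:
    """True iff any drug mention in the report maps to ``canonical_name``.

    Counting is at the report level: multiple mentions of the same drug
    count once.
    """
    if canonical_name not in vocab:
        raise KeyError(f"unknown canonical drug name {canonical_name!r}")
    return any(
        map_drug_name(vocab, mention) == canonical_name
        for mention in report.drug_mentions
    )


def report_has_event(event: EventDefinition, report: ReportRecord) -> bool:
    """True iff any reaction PT of the report belongs to the event."""
    return any(normalize_name(pt) in event.pts for pt in report.reaction_pts)
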
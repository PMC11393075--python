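"""Drug-class and event-concept dictionaries.

Drugs are grouped into the study's pharmacological classes (active
vitamin D3 analogs, NSAIDs, renin–angiotensin system inhibitors, loop
diuretics, thiazide and thiazide-related diuretics, magnesium oxide);
adverse events and comorbidities are grouped into SMQ-style concepts
(acute kidney injury, chronic kidney disease, hypertension, diabetes,
heart failure), each a set of MedDRA preferred-term (PT) names.

The bundled PT lists are SYNTHETIC STUBS — small, plausible PT sets that
keep the pipeline runnable without a licensed MedDRA distribution.  They
are not authoritative; users holding a MedDRA licence should load their
own lists via :func:`load_dictionary`.

Matching is exact on normalised text (case-folded, whitespace-collapsed),
never substring: PT names are a controlled vocabulary, and substring
matching would create false positives.
"""

from __future__ import annotations

import csv
import re
from importlib import resources
from pathlib import Path
from typing import Mapping

from .reports import ReportCase

__all__ = [
    "VITAMIN_D3_ANALOGS",
    "DRUG_CLASSES",
    "EVENT_CONCEPTS",
    "COMORBIDITY_CONCEPTS",
    "normalize_name",
    "load_dictionary",
    "load_drug_dictionary",
    "load_event_dictionary",
    "classify_drug",
    "case_has_event",
]

VITAMIN_D3_ANALOGS = ("eldecalcitol", "alfacalcidol", "calcitriol")

DRUG_CLASSES = (
    "active_vitamin_d3", "nsaid", "rasi",
    "loop_diuretic", "thiazide_like_diuretic", "magnesium_oxide",
)

EVENT_CONCEPTS = ("aki", "ckd", "hypertension", "diabetes", "heart_failure")

# evaluated against medical history (HIST); aki is evaluated against
# reported adverse events (REAC)
COMORBIDITY_CONCEPTS = ("ckd", "hypertension", "diabetes", "heart_failure")

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-fold and collapse internal whitespace.  Idempotent."""
    return _WS.sub(" ", name.strip()).casefold()


def load_dictionary(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a ``class_or_concept,name`` CSV into normalised name sets."""
    sets: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("class_or_concept", "name"):
            if col not in (reader.fieldnames or ()):
                raise ValueError(f"dictionary file missing column {col!r}")
        for row in reader:
            sets.setdefault(row["class_or_concept"].strip(), set()).add(
                normalize_name(row["name"])
            )
    return {k: frozenset(v) for k, v in sets.items()}


def _bundled(filename: str) -> dict[str, frozenset[str]]:
    with resources.as_file(
        resources.files("jaderpv").joinpath("data", filename)
    ) as p:
        return load_dictionary(p)


def load_drug_dictionary(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Drug-class dictionary; bundled stub if no path given.

    The NSAID set deliberately excludes aspirin: in this analysis
    aspirin is treated as an antiplatelet agent, not an NSAID.
    """
    d = load_dictionary(path) if path is not None else _bundled("drug_classes.csv")
    if "aspirin" in d.get("nsaid", frozenset()):
        raise ValueError("nsaid class must not contain aspirin")
    missing = [c for c in DRUG_CLASSES if not d.get(c)]
    if missing:
        raise ValueError(f"drug dictionary missing classes: {missing}")
    return d


def load_event_dictionary(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Event-concept dictionary; bundled stub if no path given."""
    d = load_dictionary(path) if path is not None else _bundled("event_terms.csv")
    missing = [c for c in EVENT_CONCEPTS if not d.get(c)]
    if missing:
        raise ValueError(f"event dictionary missing concepts: {missing}")
    return d


def classify_drug(
    generic_name: str, drug_dict: Mapping[str, frozenset[str]]
) -> frozenset[str]:
    """All classes whose name set contains the normalised generic name."""
    name = normalize_name(generic_name)
    return frozenset(cls for cls, names in drug_dict.items() if name in names)


def case_has_event(
    case: ReportCase, concept: str, event_dict: Mapping[str, frozenset[str]]
) -> bool:
    """Whether a case carries the concept.

    Adverse-event concepts (aki) are looked up among the case's reported
    events; comorbidity concepts among its medical-history terms.
    """
    if concept not in event_dict:
        raise KeyError(f"unknown event concept: {concept!r}")
    names = event_dict[concept]
    entries = case.histories if concept in COMORBIDITY_CONCEPTS else case.events
    return any(normalize_name(e.pt_name) in names for e in entries)
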
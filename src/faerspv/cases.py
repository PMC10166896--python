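"""Case and exposure definitions.

Defines the hepatic-failure adverse-event case (five mutually exclusive
MedDRA preferred terms), the immune-checkpoint-inhibitor (ICI) drug
dictionary (generic + brand names for the 8 FDA-approved agents), and the
rules classifying each report's ICI regimen:

* monotherapy — exactly one distinct ICI reported as primary or secondary
  suspect;
* combination — two or more distinct suspect ICIs, at least one of them the
  primary suspect;
* ambiguous — two or more suspect ICIs but none primary suspect (the regimen
  definitions do not cover this pattern; such reports are excluded from
  regimen-stratified contrasts but retained for class-level ones);
* none — no ICI in a suspect role.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .io import DrugMention, SafetyReport

SUSPECT_ROLES = frozenset({"PS", "SS"})

ICI_CLASSES = ("anti-PD-1", "anti-PD-L1", "anti-CTLA-4")


@dataclass(frozen=True)
class EventDefinition:
    """An adverse event defined by a set of MedDRA preferred terms."""

    name: str
    pts: frozenset[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.pts:
            raise ValueError("event definition needs at least one PT")
        for _, code in self.pts:
            if not (10_000_000 <= code <= 99_999_999):
                raise ValueError(f"MedDRA PT codes are 8-digit integers, got {code}")

    @property
    def names_lower(self) -> frozenset[str]:
        return frozenset(name.lower() for name, _ in self.pts)

    @property
    def codes(self) -> frozenset[int]:
        return frozenset(code for _, code in self.pts)


#: Hepatic failure, defined as five mutually exclusive preferred terms.
HEPATIC_FAILURE = EventDefinition(
    name="hepatic failure",
    pts=frozenset(
        {
            ("hepatic failure", 10019663),
            ("acute hepatic failure", 10000804),
            ("subacute hepatic failure", 10056956),
            ("acute on chronic liver failure", 10077305),
            ("chronic hepatic failure", 10057573),
        }
    ),
)


class DrugDictionary:
    """Case-insensitive lookup from verbatim drug name to (substance, class)."""

    def __init__(self, entries: dict[str, tuple[str, str]]):
        self._entries = {k.strip().upper(): v for k, v in entries.items()}
        classes: dict[str, str] = {}
        for substance, cls in self._entries.values():
            if substance in classes and classes[substance] != cls:
                raise ValueError(f"substance {substance!r} mapped to two classes")
            classes[substance] = cls
        self._substance_class = classes

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        entries: dict[str, tuple[str, str]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                entries[row["verbatim_name"]] = (row["substance"], row["class"])
        return cls(entries)

    @classmethod
    def default(cls) -> "DrugDictionary":
        return cls.from_csv(Path(__file__).parent / "data" / "ici_dictionary.csv")

    def lookup(self, verbatim_name: str) -> tuple[str, str] | None:
        return self._entries.get(verbatim_name.strip().upper())

    def substance_class(self, substance: str) -> str | None:
        return self._substance_class.get(substance)

    @property
    def substances(self) -> frozenset[str]:
        return frozenset(self._substance_class)


@dataclass(frozen=True)
class ExposureLabel:
    """The ICI exposure classification of one report."""

    ici_substances: frozenset[str]
    regimen: str  # monotherapy | combination | ambiguous | none
    classes: frozenset[str]
    concomitant_substances: frozenset[str]

    @property
    def regimen_key(self) -> str:
        """Canonical label: the substance for monotherapy, a '+'-joined
        sorted set for combinations, else the regimen kind."""
        if self.regimen == "monotherapy":
            return next(iter(self.ici_substances))
        if self.regimen == "combination":
            return "+".join(sorted(self.ici_substances))
        return self.regimen

    @property
    def ici_exposed(self) -> bool:
        return bool(self.ici_substances)


def is_event_case(report: SafetyReport, event: EventDefinition = HEPATIC_FAILURE) -> bool:
    """True iff any reaction PT matches the event set by name (case-
    insensitive) or numeric code.  Multiple matching PTs still count once."""
    names = event.names_lower
    codes = event.codes
    for pt_name, pt_code in report.reaction_pts:
        if pt_name.lower().strip() in names:
            return True
        if pt_code is not None and pt_code in codes:
            return True
    return False


def classify_exposure(
    report: SafetyReport | Sequence[DrugMention],
    dictionary: DrugDictionary | None = None,
    concomitant_roles: frozenset[str] = frozenset({"C"}),
) -> ExposureLabel:
    """Classify a report's ICI regimen from its drug mentions.

    Deterministic and invariant to the order of drug rows.  Non-ICI drugs in
    a concomitant role are normalized by uppercase-trim (kept verbatim when
    the dictionary does not map them).
    """
    if dictionary is None:
        dictionary = DrugDictionary.default()
    mentions = report.drugs if isinstance(report, SafetyReport) else list(report)

    suspects: dict[str, set[str]] = {}  # substance -> roles seen
    concomitants: set[str] = set()
    for m in mentions:
        hit = dictionary.lookup(m.verbatim_name)
        if hit is not None and m.role in SUSPECT_ROLES:
            suspects.setdefault(hit[0], set()).add(m.role)
        elif hit is None and m.role in concomitant_roles:
            concomitants.add(m.verbatim_name.strip().upper())

    substances = frozenset(suspects)
    if not substances:
        regimen = "none"
    elif len(substances) == 1:
        regimen = "monotherapy"
    elif any("PS" in roles for roles in suspects.values()):
        regimen = "combination"
    else:
        regimen = "ambiguous"

    classes = frozenset(
        cls for s in substances if (cls := dictionary.substance_class(s)) is not None
    )
    return ExposureLabel(
        ici_substances=substances,
        regimen=regimen,
        classes=classes,
        concomitant_substances=frozenset(concomitants),
    )


def top_concomitants(
    labels: Iterable[ExposureLabel],
    k: int = 20,
) -> list[str]:
    """The ``k`` most frequent concomitant agents among ICI-exposed reports.

    Counting is per case (an agent mentioned twice in one report counts
    once); ties break alphabetically.
    """
    if k <= 0:
        raise ValueError("k must be a positive integer")
    counts: Counter[str] = Counter()
    for label in labels:
        if label.ici_exposed:
            counts.update(label.concomitant_substances)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]
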
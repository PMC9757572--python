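"""Core value types for clinical code systems.

Read v2 / CTV3 ("Read3") codes are 5-character hierarchical codes used in UK
primary care; short codes are conventionally right-padded with dots
("G2y..", "J570."). ICD-10 and ICD-10-CM codes are stored dotless
("A879", "W540XXA") with 3-character categories and finer subdivisions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional

from .errors import MalformedCodeError, VersionConflictError

__all__ = [
    "CodeSystem",
    "Concept",
    "Ontology",
    "MatchLevel",
    "ReadDomain",
    "normalize_read_code",
    "normalize_icd10",
    "classify_read_domain",
    "truncate_icd10",
    "match_level",
]

READ_CODE_LENGTH = 5


class CodeSystem(str, enum.Enum):
    """The code systems the toolkit maps between."""

    READ2 = "READ2"
    READ3 = "READ3"
    ICD9 = "ICD9"
    ICD10 = "ICD10"
    ICD10CM = "ICD10CM"
    ICDO3 = "ICDO3"
    SNOMED = "SNOMED"
    OPCS4 = "OPCS4"

    @classmethod
    def parse(cls, label: str) -> "CodeSystem":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise MalformedCodeError(f"unknown code system: {label!r}") from None


#: Systems whose codes denote ICD diagnoses (for dual-target detection).
ICD_SYSTEMS = frozenset({CodeSystem.ICD9, CodeSystem.ICD10, CodeSystem.ICD10CM})

_READ_PREFIXES = {"2/": CodeSystem.READ2, "3/": CodeSystem.READ3}


class ReadDomain(str, enum.Enum):
    DISEASE = "DISEASE"
    NON_DISEASE = "NON_DISEASE"


class MatchLevel(enum.IntEnum):
    """Agreement level between two ICD-10 codes, ordered by strength."""

    MISMATCH = 0
    PREFIX3 = 1
    PREFIX4 = 2
    EXACT = 3


@dataclass(frozen=True)
class Concept:
    """One coded term in a code system."""

    system: CodeSystem
    code: str
    description: str = ""
    active: bool = True
    parent_code: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.code or any(c.isspace() for c in self.code):
            raise MalformedCodeError(f"bad concept code: {self.code!r}")


@dataclass
class Ontology:
    """A dictionary of concepts for one code system, keyed by code.

    Codes are unique and every non-missing ``parent_code`` must resolve to a
    stored concept once :meth:`validate` is called.
    """

    system: CodeSystem
    concepts: Dict[str, Concept] = field(default_factory=dict)

    def add(self, concept: Concept) -> None:
        from .errors import DuplicateKeyError

        if concept.code in self.concepts:
            raise DuplicateKeyError(f"duplicate code in ontology: {concept.code!r}")
        self.concepts[concept.code] = concept

    def __contains__(self, code: str) -> bool:
        return code in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self) -> Iterator[Concept]:
        return iter(self.concepts.values())

    def get(self, code: str) -> Optional[Concept]:
        return self.concepts.get(code)

    def children(self, code: str) -> list[Concept]:
        return [c for c in self.concepts.values() if c.parent_code == code]

    def validate(self) -> None:
        for c in self.concepts.values():
            if c.parent_code is not None and c.parent_code not in self.concepts:
                raise MalformedCodeError(
                    f"dangling parent {c.parent_code!r} for {c.code!r}"
                )


def normalize_read_code(raw: str, version: CodeSystem) -> str:
    """Canonicalize a Read code to its 5-character dot-padded form.

    An optional ``2/`` or ``3/`` version prefix (as printed in published
    examples like ``3/G2y..``) is stripped and must agree with *version*.
    """
    if version not in (CodeSystem.READ2, CodeSystem.READ3):
        raise ValueError(f"version must be READ2 or READ3, got {version}")
    code = raw.strip()
    if code[:2] in _READ_PREFIXES:
        embedded = _READ_PREFIXES[code[:2]]
        if embedded is not version:
            raise VersionConflictError(
                f"code {raw!r} carries prefix for {embedded.value}, "
                f"declared {version.value}"
            )
        code = code[2:]
    if not code:
        raise MalformedCodeError(f"empty Read code: {raw!r}")
    if len(code) > READ_CODE_LENGTH:
        raise MalformedCodeError(f"Read code longer than 5 characters: {raw!r}")
    return code.ljust(READ_CODE_LENGTH, ".")


def normalize_icd10(raw: str) -> str:
    """Canonicalize an ICD-10/ICD-10-CM code: trim and delete dots."""
    code = raw.strip().replace(".", "")
    if not code:
        raise MalformedCodeError(f"empty ICD-10 code: {raw!r}")
    return code


def classify_read_domain(code: str, has_icd_lookup: bool) -> ReadDomain:
    """Classify a normalized Read code as disease-related or not.

    Codes starting with a capital letter A-Z sit in the Read disease
    chapters; codes that already map into ICD via lookup tables are
    disease-related regardless of chapter (e.g. some symptom-chapter codes
    carry ICD mappings).
    """
    if len(code) != READ_CODE_LENGTH:
        raise MalformedCodeError(f"Read code not normalized: {code!r}")
    if has_icd_lookup:
        return ReadDomain.DISEASE
    if "A" <= code[0] <= "Z":
        return ReadDomain.DISEASE
    return ReadDomain.NON_DISEASE


def truncate_icd10(code: str, width: int) -> str:
    """Truncate a canonical (dotless) ICD-10 code to at most *width* chars."""
    if not code:
        raise MalformedCodeError("empty ICD-10 code")
    if width < 1:
        raise ValueError(f"width must be >= 1, got {width}")
    return code[:width]


def match_level(auto_code: str, manual_code: str) -> MatchLevel:
    """Grade agreement between two canonical ICD-10 codes.

    EXACT on identity; PREFIX4 when the first four characters agree and both
    codes are at least four characters long (so a bare 3-character category
    never spuriously 4-matches); PREFIX3 when the categories agree;
    MISMATCH otherwise.
    """
    if not auto_code or not manual_code:
        raise MalformedCodeError("empty ICD-10 code in comparison")
    if auto_code == manual_code:
        return MatchLevel.EXACT
    if (
        len(auto_code) >= 4
        and len(manual_code) >= 4
        and auto_code[:4] == manual_code[:4]
    ):
        return MatchLevel.PREFIX4
    if auto_code[:3] == manual_code[:3]:
        return MatchLevel.PREFIX3
    return MatchLevel.MISMATCH
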
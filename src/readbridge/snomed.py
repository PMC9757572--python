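"""Cross-mapping Read codes to ICD-10 through SNOMED CT.

Read v3 (CTV3) codes largely survive in SNOMED CT; Read v2 codes do not,
so v2 inputs are only mappable through a manual-override table. Concepts
carry an active flag; inactive concepts may name a replacement, and
replacement chains are followed transitively (with cycle detection) to the
first active concept. ICD-10 targets come from a SNOMED-to-ICD-10 reference
set; concepts without a reference-set row are counted as missing. When
several SNOMED candidates fit a source term, a broad policy picks the
smallest sufficiently general concept and a narrow policy the most specific
one, using ancestor counts over the concept hierarchy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .errors import ReplacementCycleError
from .terminology import CodeSystem

__all__ = [
    "SnomedConcept",
    "SnomedStatus",
    "MappingPolicy",
    "CrossmapRecord",
    "CrossmapSummary",
    "read3_to_snomed",
    "resolve_inactive",
    "snomed_to_icd10",
    "crossmap",
    "select_by_policy",
]


@dataclass(frozen=True)
class SnomedConcept:
    concept_id: str
    description: str = ""
    active: bool = True
    replaced_by: Optional[str] = None
    parents: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.active and self.replaced_by is not None:
            raise ValueError(
                f"active concept {self.concept_id} cannot carry a replacement"
            )


class SnomedStatus(str, enum.Enum):
    DIRECT = "DIRECT"
    INACTIVE_RESOLVED = "INACTIVE_RESOLVED"
    INACTIVE_UNRESOLVED = "INACTIVE_UNRESOLVED"
    MISSING = "MISSING"
    READ2_UNMAPPABLE = "READ2_UNMAPPABLE"


class MappingPolicy(str, enum.Enum):
    BROAD = "BROAD"
    NARROW = "NARROW"


@dataclass
class CrossmapRecord:
    read_code: str
    read_version: CodeSystem
    snomed_id: Optional[str] = None
    snomed_status: SnomedStatus = SnomedStatus.MISSING
    icd10_codes: List[str] = field(default_factory=list)
    review_needed: bool = False

    @property
    def icd10_status(self) -> str:
        return "MAPPED" if self.icd10_codes else "MISSING"


@dataclass
class CrossmapSummary:
    """Fractions over the crossmapped code list; denominators reported both
    over all inputs and over the Read3-only subset."""

    n_codes: int = 0
    n_read2_unmappable: int = 0
    n_read3: int = 0
    n_snomed_missing: int = 0
    n_inactive_resolved: int = 0
    n_icd10_missing: int = 0

    def fractions(self) -> Dict[str, float]:
        def frac(k: int, n: int) -> float:
            return k / n if n else 0.0

        n_with_concept = self.n_read3 - self.n_snomed_missing
        return {
            "read2_unmappable": frac(self.n_read2_unmappable, self.n_codes),
            "snomed_missing_of_read3": frac(self.n_snomed_missing, self.n_read3),
            "inactive_resolved_of_read3": frac(self.n_inactive_resolved, self.n_read3),
            "icd10_missing_of_read3": frac(self.n_icd10_missing, self.n_read3),
            "icd10_missing_of_resolved": frac(self.n_icd10_missing, n_with_concept),
        }


def read3_to_snomed(
    code: str, table: Dict[str, str], registry: Dict[str, SnomedConcept]
) -> Optional[SnomedConcept]:
    """Look one Read3 code up in the Read3-to-SNOMED map; None when absent."""
    concept_id = table.get(code)
    if concept_id is None:
        return None
    return registry.get(concept_id)


def resolve_inactive(
    concept: SnomedConcept, registry: Dict[str, SnomedConcept]
) -> Tuple[SnomedConcept, bool]:
    """Follow an inactive concept's replacement chain to an active one.

    Returns (concept, resolved). Active input returns unchanged with
    resolved=False. Inactive concepts without a replacement are returned
    unchanged (callers flag them for review). Cycles raise.
    """
    if concept.active:
        return concept, False
    seen: Set[str] = {concept.concept_id}
    chain = [concept.concept_id]
    current = concept
    while not current.active:
        if current.replaced_by is None:
            return current, False
        nxt = registry.get(current.replaced_by)
        if nxt is None:
            return current, False
        if nxt.concept_id in seen:
            raise ReplacementCycleError(chain + [nxt.concept_id])
        seen.add(nxt.concept_id)
        chain.append(nxt.concept_id)
        current = nxt
    return current, True


def snomed_to_icd10(concept_id: str, refset: Sequence[Tuple[str, str]]) -> List[str]:
    """All ICD-10 reference-set targets for a concept, in table order."""
    return [icd for cid, icd in refset if cid == concept_id]


def crossmap(
    codes: Sequence[Tuple[str, CodeSystem]],
    read3_map: Dict[str, str],
    registry: Dict[str, SnomedConcept],
    refset: Sequence[Tuple[str, str]],
    overrides: Optional[Dict[str, str]] = None,
) -> Tuple[List[CrossmapRecord], CrossmapSummary]:
    """Cross-map Read codes to ICD-10 via SNOMED CT.

    Composition: Read3-to-SNOMED lookup, inactive-concept resolution,
    reference-set ICD-10 fetch. Read2 codes have no automated path; a
    manual-override map (read code -> concept id) is the only way in.
    """
    overrides = overrides or {}
    # Pre-group the refset so crossmap stays linear in its input sizes.
    refset_by_id: Dict[str, List[str]] = {}
    for cid, icd in refset:
        refset_by_id.setdefault(cid, []).append(icd)

    records: List[CrossmapRecord] = []
    summary = CrossmapSummary(n_codes=len(codes))
    for code, version in codes:
        rec = CrossmapRecord(read_code=code, read_version=version)
        if version is CodeSystem.READ2 and code not in overrides:
            rec.snomed_status = SnomedStatus.READ2_UNMAPPABLE
            rec.review_needed = True
            summary.n_read2_unmappable += 1
            records.append(rec)
            continue
        if version is CodeSystem.READ3:
            summary.n_read3 += 1
        if code in overrides:
            concept: Optional[SnomedConcept] = registry.get(overrides[code])
        else:
            concept = read3_to_snomed(code, read3_map, registry)
        if concept is None:
            rec.snomed_status = SnomedStatus.MISSING
            rec.review_needed = True
            if version is CodeSystem.READ3:
                summary.n_snomed_missing += 1
            records.append(rec)
            continue
        resolved, did_resolve = resolve_inactive(concept, registry)
        if did_resolve:
            rec.snomed_status = SnomedStatus.INACTIVE_RESOLVED
            if version is CodeSystem.READ3:
                summary.n_inactive_resolved += 1
        elif not resolved.active:
            rec.snomed_status = SnomedStatus.INACTIVE_UNRESOLVED
            rec.review_needed = True
        else:
            rec.snomed_status = SnomedStatus.DIRECT
        rec.snomed_id = resolved.concept_id
        rec.icd10_codes = list(refset_by_id.get(resolved.concept_id, []))
        if not rec.icd10_codes and version is CodeSystem.READ3:
            summary.n_icd10_missing += 1
        records.append(rec)
    return records, summary


def _ancestors(concept_id: str, registry: Dict[str, SnomedConcept]) -> Set[str]:
    out: Set[str] = set()
    stack = list(registry[concept_id].parents) if concept_id in registry else []
    while stack:
        pid = stack.pop()
        if pid in out:
            continue
        out.add(pid)
        if pid in registry:
            stack.extend(registry[pid].parents)
    return out


def select_by_policy(
    candidates: Sequence[SnomedConcept],
    registry: Dict[str, SnomedConcept],
    policy: MappingPolicy,
) -> SnomedConcept:
    """Pick one concept from several candidates by breadth policy.

    BROAD prefers a candidate that is an ancestor of all the others (the
    smallest broad term); failing that, the candidate with the fewest
    ancestors. NARROW picks the candidate with the most ancestors (the most
    specific term). Ties break by concept id for reproducibility.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    anc = {c.concept_id: _ancestors(c.concept_id, registry) for c in candidates}
    if policy is MappingPolicy.BROAD:
        common = [
            c
            for c in candidates
            if all(
                c.concept_id in anc[o.concept_id]
                for o in candidates
                if o.concept_id != c.concept_id
            )
        ]
        pool = common if (len(candidates) > 1 and common) else list(candidates)
        return min(pool, key=lambda c: (len(anc[c.concept_id]), c.concept_id))
    return min(candidates, key=lambda c: (-len(anc[c.concept_id]), c.concept_id))
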
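"""The automated Read-to-ICD mapping workflow.

Stages, in order: lookup-table mapping (UK Biobank / TRUD style), bridging
of ICD-9-only targets to ICD-10, disease classification of still-unmapped
codes, fuzzy trigram mapping of unmapped disease codes, and flag-based
refinement. Refinement keeps only targets whose TRUD flags vouch for them —
mapping status E (exact), G (more general), or D/A (default/alternative)
when both the refine and add-code flags read C (completely refined,
complete); status R ("requires checking") is always excluded. Hybrid mode
falls back to the full target list for codes refinement would drop
entirely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .errors import FlagLookupError, UnknownCodeError
from .io import MappingEntry, MappingRecord
from .terminology import (
    ICD_SYSTEMS,
    CodeSystem,
    Ontology,
    ReadDomain,
    classify_read_domain,
)
from .trigram import DEFAULT_THRESHOLD, TrigramIndex, build_index, search

__all__ = [
    "RefinementStrategy",
    "RefinementReport",
    "LookupReport",
    "PipelineConfig",
    "CurationResult",
    "map_via_lookups",
    "remap_icd9_to_icd10",
    "prefer_unspecified_child",
    "map_unmapped_disease_codes",
    "apply_flag_refinement",
    "run_pipeline",
    "corpus_summary",
]

#: Source terms whose wording marks them as deliberately high-level, e.g.
#: "Viral meningitis NOS"; these prefer an "unspecified" ICD-10 leaf over
#: the bare 3-character category.
_HIGH_LEVEL_MARKERS = ("nos", "unspecified", "other")


class RefinementStrategy(str, enum.Enum):
    FULL = "FULL"
    REFINED = "REFINED"
    HYBRID = "HYBRID"


@dataclass
class LookupReport:
    """Side channel of the lookup stage."""

    unmapped_codes: List[Tuple[str, CodeSystem]] = field(default_factory=list)
    dual_target_codes: List[str] = field(default_factory=list)


@dataclass
class RefinementReport:
    """Bookkeeping for flag-based refinement."""

    excluded_codes: List[str] = field(default_factory=list)
    n_input: int = 0

    @property
    def excluded_fraction(self) -> float:
        return len(self.excluded_codes) / self.n_input if self.n_input else 0.0


def _entry_matches(entry: MappingEntry, code: str, version: CodeSystem) -> bool:
    if entry.source_code != code:
        return False
    return entry.source_version is None or entry.source_version is version


def map_via_lookups(
    codes: Sequence[Tuple[str, CodeSystem]],
    tables: Sequence[MappingEntry],
) -> Tuple[List[MappingRecord], LookupReport]:
    """Attach every lookup target to each input code, in table order.

    One-to-many mappings are preserved intact. Codes with no entry are
    listed in the report, not emitted. Codes mapping to both an ICD system
    and OPCS-4 (procedure) targets are flagged as dual-target.
    """
    by_code: Dict[str, List[MappingEntry]] = {}
    for entry in tables:
        by_code.setdefault(entry.source_code, []).append(entry)

    records: List[MappingRecord] = []
    report = LookupReport()
    for code, version in codes:
        matches = [e for e in by_code.get(code, []) if _entry_matches(e, code, version)]
        if not matches:
            report.unmapped_codes.append((code, version))
            continue
        records.append(
            MappingRecord(
                read_code=code,
                read_version=version,
                targets=[(e.target_code, e.target_system) for e in matches],
                method="LOOKUP",
            )
        )
        systems = {e.target_system for e in matches}
        if systems & ICD_SYSTEMS and CodeSystem.OPCS4 in systems:
            report.dual_target_codes.append(code)
    return records, report


def remap_icd9_to_icd10(
    icd9_code: str,
    icd9_dict: Ontology,
    icd10_dict: Ontology,
    bridge: Sequence[MappingEntry],
    icd10_index: Optional[TrigramIndex] = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> List[Tuple[str, bool]]:
    """Bridge an ICD-9 code to ICD-10, returning (code, review_needed) pairs.

    Bridge-table entries win verbatim; otherwise the ICD-9 description is
    fuzzy-matched against the ICD-10 dictionary and the best candidate is
    returned, flagged for review when its score falls below *threshold*.
    """
    bridged = [e for e in bridge if e.source_code == icd9_code]
    if bridged:
        return [(e.target_code, False) for e in bridged]
    concept = icd9_dict.get(icd9_code)
    if concept is None:
        raise UnknownCodeError(f"ICD-9 code {icd9_code!r} not in dictionary")
    if icd10_index is None:
        icd10_index = build_index(icd10_dict)
    hits = search(icd10_index, concept.description, top_k=1, threshold=threshold)
    return [(h.code, h.review_needed) for h in hits]


def prefer_unspecified_child(
    candidate: str, icd10_dict: Ontology, source_desc: str
) -> str:
    """Swap a 3-character category for its lone "unspecified" leaf.

    Applies only when the source description is itself high-level ("NOS",
    "unspecified", "other", or a trailing ellipsis) and the category has
    exactly one child whose description contains "unspecified"; ambiguous
    categories are left unchanged.
    """
    if len(candidate) != 3 or candidate not in icd10_dict:
        return candidate
    desc = source_desc.strip().lower()
    if not (any(m in desc for m in _HIGH_LEVEL_MARKERS) or desc.endswith("...")):
        return candidate
    unspecified = [
        c
        for c in icd10_dict.children(candidate)
        if "unspecified" in c.description.lower()
    ]
    if len(unspecified) == 1:
        return unspecified[0].code
    return candidate


def map_unmapped_disease_codes(
    codes: Sequence[Tuple[str, CodeSystem, str]],
    icd10_index: TrigramIndex,
    threshold: float = DEFAULT_THRESHOLD,
    icd10_dict: Optional[Ontology] = None,
) -> List[MappingRecord]:
    """Fuzzy-map disease codes that no lookup table covers.

    Each code gets the single best trigram candidate (after the
    unspecified-leaf preference when a dictionary is supplied); candidates
    scoring below *threshold* — and codes with no candidate at all — are
    flagged for manual review.
    """
    records: List[MappingRecord] = []
    for code, version, description in codes:
        hits = search(icd10_index, description, top_k=1, threshold=threshold)
        if not hits:
            records.append(
                MappingRecord(
                    read_code=code,
                    read_version=version,
                    targets=[],
                    method="FUZZY",
                    similarity=0.0,
                    review_needed=True,
                )
            )
            continue
        best = hits[0]
        target = best.code
        if icd10_dict is not None:
            target = prefer_unspecified_child(target, icd10_dict, description)
        records.append(
            MappingRecord(
                read_code=code,
                read_version=version,
                targets=[(target, icd10_index.system)],
                method="FUZZY",
                similarity=best.score,
                review_needed=best.review_needed,
            )
        )
    return records


def _qualifies(entry: MappingEntry) -> bool:
    s = entry.mapping_status
    if s in ("E", "G"):
        return True
    if s in ("D", "A"):
        return entry.refine_flag == "C" and entry.add_code_flag == "C"
    return False


def apply_flag_refinement(
    records: Sequence[MappingRecord],
    entries: Sequence[MappingEntry],
    strategy: RefinementStrategy,
) -> Tuple[List[MappingRecord], RefinementReport]:
    """Filter record targets by TRUD flag quality.

    FULL keeps everything. REFINED keeps only flag-qualified targets and
    drops (and counts) records left with none. HYBRID keeps the refined
    target list when non-empty and otherwise falls back to the full list,
    so hybrid coverage equals full coverage. Qualification is evaluated per
    target, not per one-to-many block.
    """
    flag_by_pair: Dict[Tuple[str, str], MappingEntry] = {}
    for entry in entries:
        flag_by_pair.setdefault((entry.source_code, entry.target_code), entry)

    report = RefinementReport(n_input=len(records))
    if strategy is RefinementStrategy.FULL:
        return list(records), report

    out: List[MappingRecord] = []
    for rec in records:
        kept: List[Tuple[str, CodeSystem]] = []
        for target_code, target_system in rec.targets:
            entry = flag_by_pair.get((rec.read_code, target_code))
            if entry is None:
                raise FlagLookupError(
                    f"no flagged entry for {rec.read_code!r} -> {target_code!r}"
                )
            if _qualifies(entry):
                kept.append((target_code, target_system))
        if kept:
            out.append(
                MappingRecord(
                    read_code=rec.read_code,
                    read_version=rec.read_version,
                    targets=kept,
                    method=rec.method,
                    similarity=rec.similarity,
                    review_needed=rec.review_needed,
                )
            )
        elif strategy is RefinementStrategy.HYBRID:
            out.append(rec)
        else:
            report.excluded_codes.append(rec.read_code)
    return out, report


@dataclass
class PipelineConfig:
    """In-memory configuration for one curation run.

    Descriptions for the input Read codes come from their own coding
    dictionaries; codes absent from both the lookup tables and the
    dictionaries are reported, never silently dropped.
    """

    codes: Sequence[Tuple[str, CodeSystem]]
    lookup_entries: Sequence[MappingEntry]
    icd10_dict: Ontology
    read_dicts: Dict[CodeSystem, Ontology]
    icd9_dict: Optional[Ontology] = None
    icd9_bridge: Sequence[MappingEntry] = ()
    manual_overrides: Sequence[MappingRecord] = ()
    strategy: RefinementStrategy = RefinementStrategy.HYBRID
    threshold: float = DEFAULT_THRESHOLD


@dataclass
class CurationResult:
    """Mapping records plus the run report."""

    records: List[MappingRecord]
    report: Dict[str, object]


def run_pipeline(config: PipelineConfig) -> CurationResult:
    """Deterministic composition of all automated mapping stages.

    Order: lookup mapping -> ICD-9 to ICD-10 bridging of ICD-9-only records
    -> disease classification of unmapped codes -> fuzzy mapping of the
    unmapped disease codes -> manual-override merge -> flag refinement per
    the configured strategy. Identical inputs produce identical outputs.
    """
    records, lookup_report = map_via_lookups(config.codes, config.lookup_entries)

    # Bridge records whose only targets are ICD-9 over to ICD-10.
    icd10_index = build_index(config.icd10_dict)
    if config.icd9_dict is not None:
        for rec in records:
            if rec.targets and all(s is CodeSystem.ICD9 for _, s in rec.targets):
                bridged: List[Tuple[str, CodeSystem]] = []
                review = rec.review_needed
                for code9, _ in rec.targets:
                    for code10, needs_review in remap_icd9_to_icd10(
                        code9,
                        config.icd9_dict,
                        config.icd10_dict,
                        config.icd9_bridge,
                        icd10_index=icd10_index,
                        threshold=config.threshold,
                    ):
                        bridged.append((code10, CodeSystem.ICD10))
                        review = review or needs_review
                if bridged:
                    rec.targets = bridged
                    rec.method = "ICD9_BRIDGE"
                    rec.review_needed = review

    # Classify unmapped codes; fuzzy-map the disease-related ones.
    fuzzy_inputs: List[Tuple[str, CodeSystem, str]] = []
    non_disease: List[Tuple[str, CodeSystem]] = []
    for code, version in lookup_report.unmapped_codes:
        if classify_read_domain(code, has_icd_lookup=False) is ReadDomain.DISEASE:
            read_dict = config.read_dicts.get(version)
            concept = read_dict.get(code) if read_dict is not None else None
            fuzzy_inputs.append((code, version, concept.description if concept else ""))
        else:
            non_disease.append((code, version))
    fuzzy_records = map_unmapped_disease_codes(
        fuzzy_inputs, icd10_index, threshold=config.threshold,
        icd10_dict=config.icd10_dict,
    )

    # Manual overrides replace whatever the automated stages produced.
    overridden = {r.read_code for r in config.manual_overrides}
    merged = [r for r in records + fuzzy_records if r.read_code not in overridden]
    merged.extend(config.manual_overrides)

    # Flags only exist for lookup-derived targets; refinement leaves the
    # fuzzy/manual records untouched.
    lookup_recs = [r for r in merged if r.method in ("LOOKUP", "ICD9_BRIDGE")]
    other_recs = [r for r in merged if r.method not in ("LOOKUP", "ICD9_BRIDGE")]
    refined, refine_report = apply_flag_refinement(
        [r for r in lookup_recs if r.method == "LOOKUP"],
        config.lookup_entries,
        config.strategy,
    )
    final = (
        refined
        + [r for r in lookup_recs if r.method == "ICD9_BRIDGE"]
        + other_recs
    )

    method_counts: Dict[str, int] = {}
    for rec in final:
        method_counts[rec.method] = method_counts.get(rec.method, 0) + 1
    report: Dict[str, object] = {
        "n_input_codes": len(config.codes),
        "n_mapped": sum(1 for r in final if r.targets),
        "method_counts": method_counts,
        "review_queue": sorted(r.read_code for r in final if r.review_needed),
        "dual_target_codes": lookup_report.dual_target_codes,
        "non_disease_codes": [c for c, _ in non_disease],
        "excluded_by_refinement": refine_report.excluded_codes,
        "excluded_fraction": refine_report.excluded_fraction,
    }
    return CurationResult(records=final, report=report)


def corpus_summary(codes: Sequence[Tuple[str, CodeSystem]]) -> Dict[str, int]:
    """Count unique Read codes per version and in total.

    A code string occurring under both versions counts once per version and
    once in each version-specific tally; the total is the sum of the
    per-version unique counts (matching how the corpus is described).
    """
    read2 = {c for c, v in codes if v is CodeSystem.READ2}
    read3 = {c for c, v in codes if v is CodeSystem.READ3}
    return {
        "n_read2": len(read2),
        "n_read3": len(read3),
        "n_total": len(read2) + len(read3),
    }
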
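"""Seeded synthetic fixtures emulating the shapes of the restricted inputs.

The real inputs — UK Biobank coding dictionaries, TRUD lookup tables,
SNOMED CT releases, and the gp_clinical event extract — are access
restricted. These generators produce structurally faithful stand-ins with
known ground truth: dot-padded 5-character Read codes with capital-letter
disease chapters, an ICD-10 dictionary with 3-character categories and
"unspecified" leaves, flagged one-to-many mapping tables with injected
wrong targets, SNOMED-style concept tables with inactive replacement
chains and a thinned ICD-10 reference set, and a patient event stream with
one deliberately over-common code to reproduce prevalence inflation.

A single master seed drives everything; each generator derives its own
stream at a fixed offset, so adding a generator never perturbs existing
fixtures and identical configs give byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import ClinicalEvent, MappingEntry
from .snomed import SnomedConcept
from .stats import QualityCategory
from .terminology import CodeSystem, Concept, Ontology

__all__ = [
    "FixtureConfig",
    "GoldEntry",
    "GoldStandard",
    "generate_ontologies",
    "generate_mapping_tables",
    "generate_snomed_tables",
    "generate_events",
    "generate_quality_labels",
    "inflation_scenario",
    "write_fixture_dir",
]

# Word bank with controlled lexical overlap so trigram similarity between
# generated descriptions spans [0, 1] meaningfully.
_NOUNS = [
    "arthritis", "dermatitis", "nephritis", "neuropathy", "carcinoma",
    "polyp", "stenosis", "fibrosis", "anaemia", "hypertension", "ulcer",
    "fracture", "infection", "allergy", "tremor", "migraine", "asthma",
    "cyst", "hernia", "oedema",
]
_SITES = [
    "knee", "skin", "kidney", "nerve", "colon", "rectum", "valve", "lung",
    "blood", "artery", "stomach", "femur", "ear", "egg", "hand", "head",
    "bronchus", "ovary", "abdomen", "ankle",
]
_QUALIFIERS = ["acute", "chronic", "benign", "malignant", "recurrent", "congenital"]

# Fraction of capital-letter (disease-chapter) Read codes that receive
# lookup entries; the remainder exercise the fuzzy-mapping stage.
_LOOKUP_COVERAGE = 0.9

# Sub-stream offsets off the master seed.
_OFF_ONTOLOGY, _OFF_MAPPING, _OFF_SNOMED, _OFF_EVENTS, _OFF_QUALITY = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the reported shape of the real corpus: roughly 37% of
    unique Read codes are disease-related; about 9% of lookup mappings are
    one-to-many; a quarter of codes carry no refinement-qualifying flag;
    42% of SNOMED-mapped concepts are inactive and 43.4% of concepts lack
    an ICD-10 reference-set entry; 2.3% of Read3 codes are absent from
    SNOMED altogether.
    """

    n_read_codes: int = 200
    disease_fraction: float = 0.375
    n_icd10: int = 120
    # Proportions over (E, G, D|C|C, A|C|C, R, other); non-qualifying mass
    # (R + other) is 0.25, the reported refined-mapping exclusion rate.
    flag_mix: Tuple[float, ...] = (0.50, 0.15, 0.07, 0.03, 0.15, 0.10)
    one_to_many_rate: float = 0.093
    injected_error_rate: float = 0.05
    inactive_snomed_rate: float = 0.42
    refset_missing_rate: float = 0.434
    snomed_missing_rate: float = 0.023
    n_patients: int = 500
    events_per_patient: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.disease_fraction, self.one_to_many_rate,
            self.injected_error_rate, self.inactive_snomed_rate,
            self.refset_missing_rate, self.snomed_missing_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must be in [0, 1]")
        if abs(sum(self.flag_mix) - 1.0) > 1e-9 or len(self.flag_mix) != 6:
            raise ValueError("flag_mix must be six proportions summing to 1")

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, offset])


@dataclass
class GoldEntry:
    """Ground truth for one generated Read code."""

    read_code: str
    read_version: CodeSystem
    true_targets: List[str] = field(default_factory=list)
    wrong_targets: List[str] = field(default_factory=list)
    wrong_target_statuses: List[str] = field(default_factory=list)
    quality: QualityCategory = QualityCategory.PERFECT
    has_lookup: bool = True


@dataclass
class GoldStandard:
    entries: Dict[str, GoldEntry] = field(default_factory=dict)

    def add(self, entry: GoldEntry) -> None:
        if entry.read_code in self.entries:
            raise ValueError(f"gold already covers {entry.read_code!r}")
        self.entries[entry.read_code] = entry

    def __getitem__(self, code: str) -> GoldEntry:
        return self.entries[code]

    def __len__(self) -> int:
        return len(self.entries)


def _description(rng: np.random.Generator, with_qualifier: bool = False) -> str:
    words = [str(rng.choice(_NOUNS)), "of", str(rng.choice(_SITES))]
    if with_qualifier:
        words.insert(0, str(rng.choice(_QUALIFIERS)))
    return " ".join(words)


_READ_BODY = "abcdefghijklmnopqrstuvwxyz0123456789"


def _read_code(rng: np.random.Generator, disease: bool, taken: set) -> str:
    while True:
        first = chr(ord("A") + rng.integers(26)) if disease else str(rng.integers(10))
        body_len = int(rng.integers(2, 5))
        body = "".join(
            _READ_BODY[rng.integers(len(_READ_BODY))] for _ in range(body_len)
        )
        code = (first + body).ljust(5, ".")
        if code not in taken:
            taken.add(code)
            return code


def generate_ontologies(
    config: FixtureConfig,
) -> Tuple[Ontology, Ontology, Ontology]:
    """Generate (read2, read3, icd10) dictionaries.

    The ICD-10 ontology has 3-character categories, each with one to five
    4-character children; 80% of categories include an "unspecified" child.
    Read descriptions are perturbed copies of ICD-10 descriptions so fuzzy
    scores spread over [0, 1].
    """
    rng = config.rng(_OFF_ONTOLOGY)
    icd10 = Ontology(system=CodeSystem.ICD10)
    leaves: List[Concept] = []
    cat_idx = 0
    while len(leaves) < config.n_icd10:
        letter = chr(ord("A") + cat_idx % 26)
        number = 10 + cat_idx // 26
        cat_code = f"{letter}{number:02d}"
        cat_desc = _description(rng)
        icd10.add(Concept(CodeSystem.ICD10, cat_code, cat_desc))
        n_children = int(rng.integers(1, 6))
        has_unspecified = rng.random() < 0.8
        for j in range(n_children):
            if len(leaves) >= config.n_icd10:
                break
            if has_unspecified and j == n_children - 1:
                child_code, child_desc = cat_code + "9", cat_desc + ", unspecified"
            else:
                child_code = cat_code + str(j)
                child_desc = f"{rng.choice(_QUALIFIERS)} {cat_desc}"
            leaf = Concept(
                CodeSystem.ICD10, child_code, child_desc, parent_code=cat_code
            )
            icd10.add(leaf)
            leaves.append(leaf)
        cat_idx += 1

    read2 = Ontology(system=CodeSystem.READ2)
    read3 = Ontology(system=CodeSystem.READ3)
    taken: set = set()
    for i in range(config.n_read_codes):
        ontology = read2 if i % 2 == 0 else read3
        disease = bool(rng.random() < config.disease_fraction)
        code = _read_code(rng, disease, taken)
        if disease:
            # Perturb the description of a true ICD-10 leaf.
            leaf = leaves[int(rng.integers(len(leaves)))]
            words = leaf.description.replace(",", "").split()
            r = rng.random()
            if r < 0.4:
                desc = leaf.description  # exact lexical match
            elif r < 0.7:
                desc = " ".join(words + [str(rng.choice(_QUALIFIERS))])
            else:
                desc = " ".join(words[: max(1, len(words) - 1)])
        else:
            desc = f"{rng.choice(['screening', 'referral', 'review', 'test'])} " \
                   f"{rng.choice(_SITES)}"
        ontology.add(Concept(ontology.system, code, desc))
    return read2, read3, icd10


_FLAG_LABELS = ("E", "G", "DCC", "ACC", "R", "other")


def _entry_for_flag(
    code: str, version: CodeSystem, target: str, flag: str,
    element: Optional[int] = None, block: Optional[int] = None,
) -> MappingEntry:
    status, refine, add = {
        "E": ("E", "", ""),
        "G": ("G", "", ""),
        "DCC": ("D", "C", "C"),
        "ACC": ("A", "C", "C"),
        "R": ("R", "", ""),
        "other": ("D", "P", "M"),  # default mapping, only partially refined
    }[flag]
    return MappingEntry(
        source_code=code,
        source_version=version,
        target_code=target,
        target_system=CodeSystem.ICD10,
        mapping_status=status,
        refine_flag=refine,
        add_code_flag=add,
        element_num=element,
        block_num=block,
        provenance="TRUD",
    )


def generate_mapping_tables(
    config: FixtureConfig,
    ontologies: Tuple[Ontology, Ontology, Ontology],
) -> Tuple[List[MappingEntry], GoldStandard]:
    """Generate flagged lookup entries plus the gold standard.

    Disease-chapter Read codes receive lookup entries with probability 0.9;
    flags follow ``flag_mix``; a ``one_to_many_rate`` fraction of covered
    codes get 2-4 true targets grouped with element/block numbers. An
    ``injected_error_rate`` fraction additionally receive one WRONG target
    drawn from an unrelated ICD-10 chapter — carrying status R with
    probability 0.9, so refinement removes most but not all injected errors.
    """
    rng = config.rng(_OFF_MAPPING)
    read2, read3, icd10 = ontologies
    leaves = [c for c in icd10 if c.parent_code is not None]
    flag_labels = np.array(_FLAG_LABELS)
    mix = np.array(config.flag_mix)

    entries: List[MappingEntry] = []
    gold = GoldStandard()
    for ontology in (read2, read3):
        for concept in ontology:
            code, version = concept.code, ontology.system
            is_chapter = "A" <= code[0] <= "Z"
            covered = is_chapter and rng.random() < _LOOKUP_COVERAGE
            entry = GoldEntry(read_code=code, read_version=version,
                              has_lookup=covered)
            if not covered:
                if is_chapter:
                    entry.quality = QualityCategory.IMPRECISE_GENERAL
                gold.add(entry)
                continue
            true_leaf = leaves[int(rng.integers(len(leaves)))]
            one_to_many = rng.random() < config.one_to_many_rate
            if one_to_many:
                siblings = [
                    c for c in leaves
                    if c.parent_code == true_leaf.parent_code
                    and c.code != true_leaf.code
                ]
                extra = min(len(siblings), int(rng.integers(1, 4)))
                targets = [true_leaf.code] + [c.code for c in siblings[:extra]]
                entry.quality = (
                    QualityCategory.MULTIPLE_COMBINATION
                    if len(targets) > 1
                    else QualityCategory.PERFECT
                )
            else:
                targets = [true_leaf.code]
            entry.true_targets = targets
            flag = str(rng.choice(flag_labels, p=mix))
            for i, target in enumerate(targets):
                element = i + 1 if len(targets) > 1 else None
                block = 1 if len(targets) > 1 else None
                entries.append(
                    _entry_for_flag(code, version, target, flag, element, block)
                )
            if rng.random() < config.injected_error_rate:
                # A wrong target from an unrelated chapter, the mechanism
                # behind artifactual prevalence inflation.
                unrelated = [
                    c for c in leaves if c.code[0] != true_leaf.code[0]
                ]
                wrong = unrelated[int(rng.integers(len(unrelated)))]
                wrong_flag = "R" if rng.random() < 0.9 else "other"
                entries.append(
                    _entry_for_flag(code, version, wrong.code, wrong_flag)
                )
                entry.wrong_targets.append(wrong.code)
                entry.wrong_target_statuses.append(wrong_flag)
            gold.add(entry)
    return entries, gold


def generate_snomed_tables(
    config: FixtureConfig,
    read3_codes: Sequence[str],
) -> Tuple[Dict[str, SnomedConcept], Dict[str, str], List[Tuple[str, str]],
           GoldStandard]:
    """Generate a SNOMED-style concept registry, Read3 map, and refset.

    A ``snomed_missing_rate`` fraction of Read3 codes have no concept at
    all; of the mapped ones, ``inactive_snomed_rate`` point at inactive
    concepts with acyclic replacement chains of length 1-2; of the final
    active concepts, ``refset_missing_rate`` lack ICD-10 reference-set
    rows. The returned gold standard records which codes were made missing,
    inactive, or refset-less.
    """
    rng = config.rng(_OFF_SNOMED)
    registry: Dict[str, SnomedConcept] = {}
    read3_map: Dict[str, str] = {}
    refset: List[Tuple[str, str]] = []
    gold = GoldStandard()
    next_id = 100000

    for code in read3_codes:
        entry = GoldEntry(read_code=code, read_version=CodeSystem.READ3)
        if rng.random() < config.snomed_missing_rate:
            entry.has_lookup = False
            gold.add(entry)
            continue
        active_id = str(next_id)
        next_id += 1
        registry[active_id] = SnomedConcept(
            concept_id=active_id, description=_description(rng), active=True
        )
        final_id = active_id
        if rng.random() < config.inactive_snomed_rate:
            chain_len = int(rng.integers(1, 3))
            head = active_id
            for _ in range(chain_len):
                inactive_id = str(next_id)
                next_id += 1
                registry[inactive_id] = SnomedConcept(
                    concept_id=inactive_id,
                    description=_description(rng),
                    active=False,
                    replaced_by=head,
                )
                head = inactive_id
            read3_map[code] = head
            entry.quality = QualityCategory.IMPRECISE_GENERAL
        else:
            read3_map[code] = active_id
        if rng.random() >= config.refset_missing_rate:
            icd = f"{chr(ord('A') + rng.integers(26))}{rng.integers(10, 99)}" \
                  f"{rng.integers(10)}"
            refset.append((final_id, icd))
            entry.true_targets = [icd]
        entry.has_lookup = True
        gold.add(entry)
    return registry, read3_map, refset, gold


def generate_events(
    config: FixtureConfig,
    read_codes: Sequence[Tuple[str, CodeSystem]],
    common_code: Optional[str] = None,
    common_weight: float = 50.0,
) -> List[ClinicalEvent]:
    """Generate a gp_clinical-style event stream.

    Codes are drawn from a seeded categorical over *read_codes*; the
    designated common code (default: the first one) gets *common_weight*
    times the baseline probability, emulating a very frequent diagnosis
    whose erroneous extra mapping inflates apparent prevalence.
    """
    rng = config.rng(_OFF_EVENTS)
    if not read_codes or config.n_patients == 0:
        return []
    if common_code is None:
        common_code = read_codes[0][0]
    weights = np.array(
        [common_weight if code == common_code else 1.0 for code, _ in read_codes]
    )
    probs = weights / weights.sum()
    start = dt.date(1990, 1, 1)
    span = (dt.date(2017, 12, 31) - start).days
    events: List[ClinicalEvent] = []
    for p in range(config.n_patients):
        eid = f"{1000 + p}"
        for _ in range(config.events_per_patient):
            code, version = read_codes[int(rng.choice(len(read_codes), p=probs))]
            when = start + dt.timedelta(days=int(rng.integers(span + 1)))
            events.append(
                ClinicalEvent(
                    eid=eid,
                    data_provider=int(rng.integers(1, 5)),
                    event_dt=when,
                    read_2=code if version is CodeSystem.READ2 else None,
                    read_3=code if version is CodeSystem.READ3 else None,
                )
            )
    return events


def generate_quality_labels(
    n: int, imprecision_rate: float, seed: int, multiple_rate: float = 0.06
) -> List[QualityCategory]:
    """Draw gold quality labels with a known imprecise-group rate.

    Each code is imprecise with probability *imprecision_rate* (subtype
    drawn uniformly), multiple with probability *multiple_rate*, perfect
    otherwise. Used for credible-interval coverage checks.
    """
    rng = np.random.default_rng([seed, _OFF_QUALITY])
    imprecise = [
        QualityCategory.IMPRECISE_GENERAL,
        QualityCategory.IMPRECISE_CLOSEST,
        QualityCategory.IMPRECISE_UNSPECIFIED,
    ]
    multiple = [
        QualityCategory.MULTIPLE_COMBINATION,
        QualityCategory.MULTIPLE_MORPHOLOGY,
        QualityCategory.MULTIPLE_BLOCK,
    ]
    labels: List[QualityCategory] = []
    for _ in range(n):
        r = rng.random()
        if r < imprecision_rate:
            labels.append(imprecise[int(rng.integers(3))])
        elif r < imprecision_rate + multiple_rate:
            labels.append(multiple[int(rng.integers(3))])
        else:
            labels.append(QualityCategory.PERFECT)
    return labels


def inflation_scenario(
    config: Optional[FixtureConfig] = None,
) -> Dict[str, object]:
    """A deterministic prevalence-inflation scenario with known truth.

    One very common Read3 code (an osteoarthritis stand-in, ``XE1DV``-like)
    carries correct joint-disorder targets plus one erroneous metabolic
    target ``E702`` flagged R; a rare Read2 code truly maps to ``E702``.
    Under full mapping the apparent E70 prevalence is dominated by the
    common code's patients; refinement removes the R-flagged target and
    recovers the true count exactly.
    """
    config = config or FixtureConfig()
    common, rare = "XE1DV", "C3700"
    entries = [
        _entry_for_flag(common, CodeSystem.READ3, "M190", "DCC",
                        element=1, block=1),
        _entry_for_flag(common, CodeSystem.READ3, "M199", "DCC",
                        element=2, block=1),
        _entry_for_flag(common, CodeSystem.READ3, "E702", "R"),
        _entry_for_flag(rare, CodeSystem.READ2, "E702", "E"),
    ]
    rng = config.rng(_OFF_EVENTS)
    n_common = max(2, int(round(config.n_patients * 0.95)))
    n_rare = max(1, int(round(config.n_patients * 0.01)))
    start = dt.date(1990, 1, 1)
    span = (dt.date(2017, 12, 31) - start).days
    events: List[ClinicalEvent] = []
    eid = 1000
    for code, version, count in (
        (common, CodeSystem.READ3, n_common),
        (rare, CodeSystem.READ2, n_rare),
    ):
        for _ in range(count):
            events.append(
                ClinicalEvent(
                    eid=str(eid),
                    data_provider=int(rng.integers(1, 5)),
                    event_dt=start + dt.timedelta(days=int(rng.integers(span + 1))),
                    read_2=code if version is CodeSystem.READ2 else None,
                    read_3=code if version is CodeSystem.READ3 else None,
                )
            )
            eid += 1
    return {
        "entries": entries,
        "events": events,
        "codes": [(common, CodeSystem.READ3), (rare, CodeSystem.READ2)],
        "true_e70_patients": n_rare,
        "full_e70_patients": n_common + n_rare,
    }


def write_fixture_dir(config: FixtureConfig, out_dir: Path) -> Dict[str, Path]:
    """Materialize one full fixture set as TSV files (plus gold standard)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    read2, read3, icd10 = generate_ontologies(config)
    entries, gold = generate_mapping_tables(config, (read2, read3, icd10))
    read3_codes = sorted(c.code for c in read3)
    registry, read3_map, refset, snomed_gold = generate_snomed_tables(
        config, read3_codes
    )
    all_codes = [(c.code, CodeSystem.READ2) for c in read2] + [
        (c.code, CodeSystem.READ3) for c in read3
    ]
    events = generate_events(config, all_codes)

    paths: Dict[str, Path] = {}

    def write(name: str, header: List[str], rows: List[List[str]]) -> None:
        path = out_dir / name
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(row) + "\n")
        paths[name] = path

    for label, onto in (("read2", read2), ("read3", read3), ("icd10", icd10)):
        write(
            f"{label}_coding.tsv",
            ["coding", "meaning", "parent"],
            [[c.code, c.description, c.parent_code or ""] for c in onto],
        )
    write(
        "lookup.tsv",
        ["read_code", "read_version", "target_code", "target_system",
         "mapping_status", "refine_flag", "add_code_flag", "element_num",
         "block_num", "provenance"],
        [
            [
                e.source_code,
                e.source_version.value if e.source_version else "",
                e.target_code, e.target_system.value, e.mapping_status,
                e.refine_flag, e.add_code_flag,
                "" if e.element_num is None else str(e.element_num),
                "" if e.block_num is None else str(e.block_num),
                e.provenance,
            ]
            for e in entries
        ],
    )
    write(
        "snomed_concepts.tsv",
        ["concept_id", "description", "active", "replaced_by", "parents"],
        [
            [c.concept_id, c.description, "1" if c.active else "0",
             c.replaced_by or "", "|".join(c.parents)]
            for c in registry.values()
        ],
    )
    write("read3_map.tsv", ["read_code", "concept_id"],
          [[k, v] for k, v in read3_map.items()])
    write("refset.tsv", ["concept_id", "icd10_code"],
          [[cid, icd] for cid, icd in refset])
    write(
        "events.tsv",
        ["eid", "data_provider", "event_dt", "read_2", "read_3"],
        [
            [e.eid, str(e.data_provider), e.event_dt.isoformat(),
             e.read_2 or "", e.read_3 or ""]
            for e in events
        ],
    )
    write(
        "gold_standard.tsv",
        ["read_code", "read_version", "true_targets", "wrong_targets",
         "wrong_target_statuses", "quality", "has_lookup"],
        [
            [
                g.read_code, g.read_version.value, "|".join(g.true_targets),
                "|".join(g.wrong_targets), "|".join(g.wrong_target_statuses),
                g.quality.value, "1" if g.has_lookup else "0",
            ]
            for g in gold.entries.values()
        ],
    )
    return paths
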
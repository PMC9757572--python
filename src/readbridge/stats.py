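"""Mapping-quality evaluation and proportion statistics.

Two taxonomies grade a mapping. The *quality category* grades a manually
curated mapping on its own terms: perfect one-to-one, imprecise (a more
general / closest / "unspecified"-qualified target had to be used), or
multiple (one source term needs several targets, a code block, or a
morphology ontology). The *agreement class* grades an automated mapping
against the manual gold standard by how many leading ICD-10 characters
agree. Uncertainty on every reported proportion is an equal-tailed Bayesian
credible interval under a flat Beta(1, 1) prior, i.e. quantiles of the
Beta(k+1, n-k+1) posterior.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd
from scipy.stats import beta as beta_dist

from .io import ClinicalEvent, MappingRecord
from .terminology import CodeSystem, MatchLevel, match_level, truncate_icd10

__all__ = [
    "QualityCategory",
    "QualityGroup",
    "AgreementClass",
    "CurationVerdict",
    "ProportionCI",
    "assign_quality_category",
    "compare_mappings",
    "proportion_ci",
    "quality_report",
    "group_report",
    "prevalence_count",
]


class QualityGroup(str, enum.Enum):
    NO_ISSUE = "NO_ISSUE"
    IMPRECISE = "IMPRECISE"
    MULTIPLE = "MULTIPLE"


class QualityCategory(str, enum.Enum):
    """How well a source term could be mapped at all."""

    PERFECT = "PERFECT"
    IMPRECISE_GENERAL = "IMPRECISE_GENERAL"
    MULTIPLE_COMBINATION = "MULTIPLE_COMBINATION"
    MULTIPLE_MORPHOLOGY = "MULTIPLE_MORPHOLOGY"
    IMPRECISE_CLOSEST = "IMPRECISE_CLOSEST"
    MULTIPLE_BLOCK = "MULTIPLE_BLOCK"
    IMPRECISE_UNSPECIFIED = "IMPRECISE_UNSPECIFIED"

    @property
    def group(self) -> QualityGroup:
        return _CATEGORY_GROUP[self]


_CATEGORY_GROUP = {
    QualityCategory.PERFECT: QualityGroup.NO_ISSUE,
    QualityCategory.IMPRECISE_GENERAL: QualityGroup.IMPRECISE,
    QualityCategory.MULTIPLE_COMBINATION: QualityGroup.MULTIPLE,
    QualityCategory.MULTIPLE_MORPHOLOGY: QualityGroup.MULTIPLE,
    QualityCategory.IMPRECISE_CLOSEST: QualityGroup.IMPRECISE,
    QualityCategory.MULTIPLE_BLOCK: QualityGroup.MULTIPLE,
    QualityCategory.IMPRECISE_UNSPECIFIED: QualityGroup.IMPRECISE,
}


class AgreementClass(str, enum.Enum):
    """Automated vs manual mapping agreement, strongest verdict first."""

    MORPHOLOGY = "MORPHOLOGY"
    MISSING_OR_INCORRECT = "MISSING_OR_INCORRECT"
    EXACT = "EXACT"
    MATCH4 = "MATCH4"
    PARTIAL_MULTI = "PARTIAL_MULTI"
    MATCH3 = "MATCH3"
    NEAR_MISS = "NEAR_MISS"


@dataclass(frozen=True)
class CurationVerdict:
    """Structured curator annotation for one manually mapped code."""

    precise: bool = True
    morphology: bool = False
    combination: bool = False
    block: bool = False
    unspecified_qualifier: bool = False
    closest_only: bool = False


def _is_block(code: str) -> bool:
    # An ICD-10 block/range target like "H80-H83".
    return "-" in code


def assign_quality_category(
    manual_targets: Sequence[Tuple[str, CodeSystem]],
    verdict: CurationVerdict,
) -> QualityCategory:
    """Deterministic decision tree from targets + curator verdict.

    Precedence: morphology (an ICD-O-3 target is present), then multi-code
    combinations, then block/range targets, then a single precise target
    (perfect), then the imprecision subtypes.
    """
    if verdict.morphology or any(s is CodeSystem.ICDO3 for _, s in manual_targets):
        return QualityCategory.MULTIPLE_MORPHOLOGY
    if verdict.combination or len(manual_targets) >= 2:
        return QualityCategory.MULTIPLE_COMBINATION
    if verdict.block or any(_is_block(c) for c, _ in manual_targets):
        return QualityCategory.MULTIPLE_BLOCK
    if verdict.precise and not (verdict.unspecified_qualifier or verdict.closest_only):
        return QualityCategory.PERFECT
    if verdict.unspecified_qualifier:
        return QualityCategory.IMPRECISE_UNSPECIFIED
    if verdict.closest_only:
        return QualityCategory.IMPRECISE_CLOSEST
    return QualityCategory.IMPRECISE_GENERAL


def compare_mappings(auto: MappingRecord, manual: MappingRecord) -> AgreementClass:
    """Grade an automated record against the manual record for one code."""
    if auto.read_code != manual.read_code:
        raise ValueError(
            f"records compare different codes: {auto.read_code!r} vs "
            f"{manual.read_code!r}"
        )
    if any(s is CodeSystem.ICDO3 for _, s in manual.targets):
        return AgreementClass.MORPHOLOGY
    if not auto.targets:
        return AgreementClass.MISSING_OR_INCORRECT
    auto_codes = [c for c, _ in auto.targets]
    manual_codes = [c for c, _ in manual.targets]
    if set(auto_codes) == set(manual_codes):
        return AgreementClass.EXACT

    def best_against(code: str, others: Sequence[str]) -> MatchLevel:
        return max(match_level(code, o) for o in others)

    manual_covered4 = all(
        best_against(m, auto_codes) >= MatchLevel.PREFIX4 for m in manual_codes
    )
    auto_levels = [best_against(a, manual_codes) for a in auto_codes]
    if manual_covered4 and all(lv >= MatchLevel.PREFIX4 for lv in auto_levels):
        return AgreementClass.MATCH4
    if (
        len(auto_codes) > 1
        and any(lv >= MatchLevel.PREFIX4 for lv in auto_levels)
        and any(lv is MatchLevel.MISMATCH for lv in auto_levels)
    ):
        return AgreementClass.PARTIAL_MULTI
    if max(auto_levels) >= MatchLevel.PREFIX3:
        return AgreementClass.MATCH3
    return AgreementClass.NEAR_MISS


@dataclass(frozen=True)
class ProportionCI:
    """k of n with percentage and flat-prior Bayesian credible bounds."""

    k: int
    n: int
    pct: float
    lower: float
    upper: float
    level: float = 0.95


def proportion_ci(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Equal-tailed credible interval for a binomial proportion.

    Flat Beta(1, 1) prior, so the posterior is Beta(k+1, n-k+1); bounds are
    its (1-level)/2 and 1-(1-level)/2 quantiles, on the percent scale.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, n >= 1; got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    tail = (1.0 - level) / 2.0
    lower, upper = beta_dist.ppf([tail, 1.0 - tail], k + 1, n - k + 1)
    return ProportionCI(
        k=k, n=n, pct=100.0 * k / n, lower=100.0 * lower, upper=100.0 * upper,
        level=level,
    )


def round_pct(x: float, mode: str = "half-up", digits: int = 1) -> float:
    """Round a percentage for display: decimal half-up or truncation."""
    q = Decimal(10) ** -digits
    d = Decimal(repr(float(x)))
    if mode == "half-up":
        return float(d.quantize(q, rounding=ROUND_HALF_UP))
    if mode == "truncate":
        return float(d.quantize(q, rounding="ROUND_DOWN"))
    raise ValueError(f"unknown rounding mode {mode!r}")


def quality_report(
    assessments: Sequence[object],
    level: float = 0.95,
    rounding: str = "half-up",
) -> pd.DataFrame:
    """Tabulate category/class labels with percentages and credible bounds.

    Accepts any sequence of enum labels (quality categories or agreement
    classes). Rows are ordered by descending count, ties by label; columns:
    label, group (blank for agreement classes), count, pct, ci_lower,
    ci_upper. Percentages use exact counts; display rounding is half-up by
    default with truncation available.
    """
    if not assessments:
        raise ValueError("assessments must be non-empty")
    n = len(assessments)
    counts: Dict[str, int] = {}
    for a in assessments:
        label = a.value if isinstance(a, enum.Enum) else str(a)
        counts[label] = counts.get(label, 0) + 1
    rows = []
    for label, k in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        ci = proportion_ci(k, n, level=level)
        try:
            group = QualityCategory(label).group.value
        except ValueError:
            group = ""
        rows.append(
            {
                "label": label,
                "group": group,
                "count": k,
                "pct": round_pct(ci.pct, rounding),
                "ci_lower": round_pct(ci.lower, rounding),
                "ci_upper": round_pct(ci.upper, rounding),
            }
        )
    return pd.DataFrame(rows)


def prevalence_count(
    events: Sequence[ClinicalEvent],
    mapping: Sequence[MappingRecord],
    icd10_prefix: str,
) -> int:
    """Distinct participants with any event mapping into an ICD-10 prefix.

    A participant counts once no matter how many qualifying events they
    have. An event qualifies when any mapped target of its Read code starts
    with *icd10_prefix* (comparison after truncating targets to the prefix
    length). This is the diagnostic used to expose prevalence inflation
    from erroneous one-to-many mappings.
    """
    width = len(icd10_prefix)
    qualifying_codes: Set[Tuple[str, CodeSystem]] = set()
    for rec in mapping:
        for target_code, target_system in rec.targets:
            if target_system in (CodeSystem.ICD10, CodeSystem.ICD10CM) and (
                truncate_icd10(target_code, width) == icd10_prefix
            ):
                qualifying_codes.add((rec.read_code, rec.read_version))
                break
    eids: Set[str] = set()
    for ev in events:
        if (
            (ev.read_2 and (ev.read_2, CodeSystem.READ2) in qualifying_codes)
            or (ev.read_3 and (ev.read_3, CodeSystem.READ3) in qualifying_codes)
        ):
            eids.add(ev.eid)
    return len(eids)


def group_report(
    categories: Sequence[QualityCategory],
    level: float = 0.95,
    rounding: str = "half-up",
) -> pd.DataFrame:
    """Aggregate quality categories to their groups with credible bounds."""
    if not categories:
        raise ValueError("categories must be non-empty")
    n = len(categories)
    counts: Dict[str, int] = {}
    for c in categories:
        counts[c.group.value] = counts.get(c.group.value, 0) + 1
    rows = []
    for group, k in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        ci = proportion_ci(k, n, level=level)
        rows.append(
            {
                "group": group,
                "count": k,
                "pct": round_pct(ci.pct, rounding),
                "ci_lower": round_pct(ci.lower, rounding),
                "ci_upper": round_pct(ci.upper, rounding),
                "ci_lower_exact": ci.lower,
                "ci_upper_exact": ci.upper,
            }
        )
    return pd.DataFrame(rows)
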
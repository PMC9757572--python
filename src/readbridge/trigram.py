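"""Pre-indexed character-trigram fuzzy search over concept descriptions.

Descriptions are normalized (lowercased, punctuation collapsed to spaces)
and decomposed into padded character trigrams per word: each token gets two
leading and one trailing boundary pad, so a token of length n contributes
n+1 trigrams. Similarity between two strings is the Jaccard coefficient of
their trigram sets, which is 1 exactly when the normalized strings are
equal. An inverted index (trigram -> codes) makes search over a whole
ontology cheap while returning results identical to a brute-force scan.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Set

from .terminology import CodeSystem, Ontology

__all__ = [
    "DEFAULT_THRESHOLD",
    "FuzzyCandidate",
    "TrigramIndex",
    "normalize_text",
    "trigrams",
    "similarity",
    "build_index",
    "search",
]

#: Review threshold: candidates scoring below this are flagged for manual
#: inspection rather than accepted automatically.
DEFAULT_THRESHOLD = 0.80

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_text(s: str) -> str:
    """Lowercase and collapse every run of non-alphanumerics to one space."""
    return _NON_ALNUM.sub(" ", s.lower()).strip()


def trigrams(s: str) -> FrozenSet[str]:
    """Padded trigram set of an already-normalized string.

    Each whitespace token is padded to ``"  " + token + " "`` and all
    contiguous 3-character windows are collected; the result is the union
    over tokens. Empty input yields the empty set.
    """
    out: Set[str] = set()
    for token in s.split():
        padded = "  " + token + " "
        out.update(padded[i : i + 3] for i in range(len(padded) - 2))
    return frozenset(out)


def similarity(a: str, b: str) -> float:
    """Jaccard trigram similarity in [0, 1]; normalization applied here.

    Two empty strings are identical (1.0); one empty string shares nothing
    with a non-empty one (0.0).
    """
    ta, tb = trigrams(normalize_text(a)), trigrams(normalize_text(b))
    if not ta and not tb:
        return 1.0
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


@dataclass(frozen=True)
class FuzzyCandidate:
    """One search hit: a concept plus its similarity to the query."""

    code: str
    description: str
    score: float
    review_needed: bool = False


@dataclass
class TrigramIndex:
    """Inverted trigram index over one ontology's descriptions."""

    system: CodeSystem
    postings: Dict[str, Set[str]] = field(default_factory=dict)
    trigram_sets: Dict[str, FrozenSet[str]] = field(default_factory=dict)
    descriptions: Dict[str, str] = field(default_factory=dict)
    built_from: str = ""


def _fingerprint(ontology: Ontology) -> str:
    h = hashlib.sha256()
    for code in sorted(ontology.concepts):
        desc = normalize_text(ontology.concepts[code].description)
        h.update(code.encode() + b"\x00" + desc.encode() + b"\x01")
    return h.hexdigest()


def build_index(ontology: Ontology) -> TrigramIndex:
    """Index every concept's normalized description for trigram search."""
    index = TrigramIndex(system=ontology.system, built_from=_fingerprint(ontology))
    for concept in ontology:
        tset = trigrams(normalize_text(concept.description))
        index.trigram_sets[concept.code] = tset
        index.descriptions[concept.code] = concept.description
        for t in tset:
            index.postings.setdefault(t, set()).add(concept.code)
    return index


def search(
    index: TrigramIndex,
    query: str,
    top_k: int = 5,
    threshold: float = DEFAULT_THRESHOLD,
) -> List[FuzzyCandidate]:
    """Top-k trigram matches for *query*, highest score first.

    Only concepts sharing at least one trigram with the query can score
    above zero, so candidates are gathered from the inverted index; scores
    are exact Jaccard coefficients, identical to a brute-force scan. Ties
    are broken by ascending code so results are reproducible. Candidates
    scoring below *threshold* are returned with ``review_needed=True``,
    never silently dropped; zero-score concepts are omitted.
    """
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    qset = trigrams(normalize_text(query))
    candidates: Set[str] = set()
    for t in qset:
        candidates.update(index.postings.get(t, ()))
    scored = []
    for code in candidates:
        tset = index.trigram_sets[code]
        if not qset and not tset:
            score = 1.0
        elif not qset or not tset:
            score = 0.0
        else:
            score = len(qset & tset) / len(qset | tset)
        if score > 0.0:
            scored.append((score, code))
    scored.sort(key=lambda sc: (-sc[0], sc[1]))
    return [
        FuzzyCandidate(
            code=code,
            description=index.descriptions[code],
            score=score,
            review_needed=score < threshold,
        )
        for score, code in scored[:top_k]
    ]
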
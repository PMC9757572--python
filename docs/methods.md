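# Methods

This note records, in the package's own words, the model and procedures
implemented in `readbridge`, the design of the synthetic generators, and
the numerical conventions, so that results are interpretable without
reading the source.

## Problem setting

UK primary-care records code diagnoses in Read v2 and CTV3 (Read3), two
hierarchical 5-character terminologies. Downstream epidemiology needs
those codes expressed in ICD-10 (or ICD-10-CM, or SNOMED CT). Official
lookup tables supply candidate targets, but three failure modes make a
naive join unsafe:

1. **One-to-many blocks.** A single Read code may list several targets,
   only some of which are correct; targets are annotated with mapping
   flags of varying trustworthiness.
2. **Coverage gaps.** Many codes have no lookup entry at all and must be
   matched by description.
3. **Erroneous targets.** A wrong target attached to a *common* source
   code transfers that code's entire patient population to the wrong
   disease, inflating rare-disease prevalence by orders of magnitude.

## Terminology conventions

- Read codes are canonicalized to exactly five characters, right-padded
  with dots (`G2y..`); an optional `2/` or `3/` prefix declares the
  version and conflicts raise a typed error.
- ICD-10 codes are canonicalized without dots (`A87.9` → `A879`). The
  first three characters are the category.
- A Read code belongs to the *disease* domain when it has an ICD lookup
  entry or its first character is a capital letter A–Z; other codes
  (processes of care, drugs, administrative) are excluded from
  description-based disease mapping.
- Agreement between two ICD-10 codes is graded on leading characters:
  `EXACT` (identical), `PREFIX4` (both at least 4 characters and equal on
  the first 4), `PREFIX3` (equal category), else `MISMATCH`.

## Lookup mapping and flag refinement

Lookup mapping joins each input code against the mapping table,
preserving table order within a code's block and keeping element/block
numbers so multi-code combinations stay grouped. Codes whose targets
include both an ICD system and OPCS-4 are reported as dual diagnosis/
procedure codes. ICD-9-only targets are bridged to ICD-10 via an explicit
equivalence table where available, otherwise by fuzzy description match.

A target *qualifies* under refinement when its mapping status is `E`
(exact) or `G` (target more general), or its status is `D` or `A`
(default / alternative) with both the refine flag and the add-code flag
equal to `C` (coded as certain). Status `R` (requires checking) never
qualifies. Three strategies are offered:

- **full** — keep every listed target;
- **refined** — keep only qualifying targets and drop codes left with
  none (the exclusion fraction is reported);
- **hybrid** — refined where at least one target qualifies, full
  otherwise, so coverage equals the full strategy by construction.

Refinement can only remove targets; the test suite asserts this subset
property on randomized flag fixtures.

## Trigram fuzzy matching

Unmapped disease-domain codes are matched against ICD-10 descriptions by
character trigrams. Normalization lowercases and collapses every run of
non-alphanumeric characters to a single space. Each token of length *n*
is padded with two leading and one trailing boundary space, contributing
*n + 1* trigrams; a string's trigram set is the union over its tokens.
Similarity is the Jaccard coefficient of the two sets (1 if both sets are
empty, 0 if exactly one is). An inverted index (trigram → posting list)
restricts scoring to concepts sharing at least one trigram with the
query, which is exact: any concept with similarity > 0 shares a trigram,
so indexed search provably equals a brute-force scan, and the suite
checks this equivalence against an independently written oracle.

Candidates are ranked by descending score with ties broken by ascending
code. The best candidate is accepted automatically only at similarity
≥ 0.80; below that the record is kept but flagged for manual review, so
the threshold governs review burden, never silent data loss. One
description-level rule runs before acceptance: when the best target is a
bare 3-character category, the source description is high-level
("unspecified", "NOS", "other", or a trailing ellipsis), and the category
has exactly one "unspecified" child, that child is preferred as the more
useful leaf.

## SNOMED CT bridge

Read3 codes map to SNOMED concepts via the published one-to-one
correspondence; Read2 codes have no such table and are reported
non-mappable unless a manual override supplies a concept. Inactive
concepts are resolved by following `replaced_by` links transitively, with
cycle detection raising a typed error and dead ends reported as
unresolved. ICD-10 targets then come from a SNOMED→ICD-10 reference set;
concepts absent from the refset are reported as such rather than guessed.
When several candidate concepts exist, two policies choose one: **broad**
prefers a common ancestor of all candidates if one is present, otherwise
the candidate with the fewest ancestors (most general); **narrow**
prefers the candidate with the most ancestors (most specific). Ties break
on concept identifier for determinism.

## Evaluation statistics

Manual mappings are graded into seven quality categories in three groups:
no issue (perfect one-to-one), imprecise (a more general target, an
"unspecified"-qualified target, or merely the closest available term),
and multiple (a combination of codes, a code block/range, or a morphology
ontology target). Automated mappings are graded against the manual gold
standard into seven agreement classes, by precedence: morphology,
missing/incorrect, exact set equality, 4-character agreement on both
sides, partially correct multi-target (at least one 4-character match and
one mismatch), 3-character (category) agreement, and near miss.

Every reported proportion *k*/*n* carries an equal-tailed credible
interval under a flat Beta(1, 1) prior: the posterior is
Beta(*k* + 1, *n* − *k* + 1) and the bounds are its 2.5% and 97.5%
quantiles (at the default 95% level), evaluated with `scipy.stats.beta`.
A Monte-Carlo oracle (10⁶ posterior draws) agrees with the quantile
bounds to within 0.1 percentage points in the tests. Display rounding
offers decimal half-up and truncation modes because published summary
tables mix the two conventions; the underlying exact values are always
retained alongside.

Prevalence is counted as distinct participants with at least one event
whose (version-aware) Read code maps into a given ICD-10 prefix. The
inflation diagnostic compares this count under full versus refined
mapping: a wrong R-flagged target on a common code inflates the full
count, and refinement collapses it back to the true value.

## Synthetic generators

All generators draw from `numpy.random.default_rng([seed, offset])` with
a distinct offset per sub-stream, so components are independently
reproducible and whole fixture directories are byte-identical across
reruns with the same seed. Default sizes (200 Read codes, 120 ICD-10
leaves, 500 patients, 3 events/patient) keep the full suite fast while
leaving room for the rate checks below to be meaningful at larger n.

Chosen rates mirror the regimes the toolkit must handle rather than any
particular dataset's secrets:

- **Lookup coverage 0.9** — most codes have lookup entries; the rest
  exercise the fuzzy path.
- **Flag mix (E, G, D/C/C, A/C/C, R, other) =
  (0.50, 0.15, 0.07, 0.03, 0.15, 0.10)** — the non-qualifying mass is
  0.25, so roughly a quarter of lookup-mapped codes drop out under the
  refined strategy, matching the regime where refinement is a
  consequential choice.
- **Injected wrong targets (rate 0.05) carry status `R` with
  probability 0.9** — encodes the empirical pattern that erroneous
  targets are overwhelmingly the ones flagged as requiring checking,
  which is what makes flag refinement effective; the 0.1 remainder keeps
  refinement from being a perfect oracle.
- **Inactive SNOMED concepts 0.42, refset-missing 0.434, absent 0.023**
  — large inactive and refset-gap fractions stress the replacement-chain
  and missingness reporting paths.
- **Read descriptions** are perturbations of their true ICD-10 leaf
  description (40% verbatim, 30% with an extra qualifier word, 30% with a
  word dropped), so trigram similarity is informative but imperfect.

The prevalence-inflation scenario is deliberately extreme: one common
code (95% of patients) whose lookup block includes a wrong R-flagged
metabolic-disorder target alongside its two correct osteoarthritis
targets, and one rare code (1% of patients) genuinely mapping to the
metabolic disorder. Full mapping then overstates the metabolic-disorder
prevalence roughly a hundredfold; refinement recovers the exact truth.

What the fixtures do **not** emulate: real terminology hierarchies and
cross-version synonymy, realistic code-frequency distributions, coding
drift over calendar time, data-provider heterogeneity, and free-text or
local codes. Conclusions about absolute mapping accuracy on real data
cannot be drawn from them; they exist to verify the machinery's contracts
(subset properties, determinism, exact search equivalence, interval
calibration) with known ground truth.

## Numerical and engineering choices

- Credible-interval coverage is itself tested: at injected imprecision
  rates of 0.1 and 0.3, the 95% interval on the imprecise-group share
  covers the truth in at least 93% of 200 seeded replicates.
- Percentage rounding goes through `decimal.Decimal` on the `repr` of
  the float, avoiding binary-float surprises at the half boundary.
- All tie-breaks (fuzzy candidates, SNOMED policy selection, report row
  order) are total orders, so every output is deterministic given its
  inputs and seed.
- Similarity is stored only on fuzzy-matched records; lookup and manual
  records reject a similarity value at construction time.

## Limitations

The flag-refinement semantics implement one published reading of the
TRUD flag vocabulary; other reasonable readings exist (e.g. treating `G`
as needing review). The unspecified-leaf preference is a heuristic and
can be disabled by using the lookup/fuzzy primitives directly. The
SNOMED bridge selects a single concept per policy rather than returning
ranked alternatives. The fuzzy threshold 0.80 is a review-routing
default, not a validated accuracy boundary.
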
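# Methods

## Assessment model

A batch is a sequence of structured outpatient records assessed under one
`RuleConfig`, which holds three independent layers:

1. **Integrity (mandatory items).** Each of the k = 16 default mandatory
   rules binds one record field and a requirement: `non_blank` for scalar
   fields, `at_least_one` for list-valued fields. A value that is absent,
   empty, or whitespace-only is missing; an empty list is a missing item.
   This deliberately broad missingness definition makes the check robust to
   export artifacts (padded cells, stray delimiters) common in real EMR
   dumps. Per record, X_i counts unsatisfied mandatory rules.

2. **Coding (code ranges).** Each of the k′ = 13 default coding rules binds
   a code-bearing field to a named code set. An item with codes present is
   compliant iff *every* code is a member of the set — one out-of-range
   member spoils the item. Membership is exact, case-sensitive string
   equality after whitespace normalization, because the administrative and
   terminology code systems define codes as case-significant identifiers.
   Rules are *strict* (a missing code is itself noncompliant) when the
   field's presence is already a mandatory item — gender and the TCM
   symptom/syndrome/treatment/dominant-disease codes — and
   *checked-if-present* for the seven administrative-only value sets
   (ethnicity, insurance type, disease severity, ID type, diagnosis type,
   payment method, nationality). The lenient default avoids double-counting
   items the integrity layer never requires; it is configurable per rule
   via `require_present`. Per record, Y_i counts noncompliant coding rules.

3. **Star scheme.** An ordered list of standards, each a conjunction of
   named mandatory and/or coding flags, with cumulative thresholds
   {1★: 5, 2★: 7, 3★: 9, 4★: 11, 5★: 14}. A record's level is the largest
   L whose threshold-length prefix of standards all hold; failing the
   one-star prefix yields zero stars, and a false standard inside a prefix
   blocks the level regardless of later standards.

Batch scores are S_i = (1 − ΣX_i/(n·k))·100, S_c = (1 − ΣY_i/(n·k′))·100,
S_t = w₁S_i + w₂S_c (default 0.5/0.5). They are computed with exact
rational arithmetic (`fractions.Fraction`) and converted to float once, so
permutation invariance and the round trip against the synthetic ground
truth hold exactly. An empty batch is an error, never a vacuous 100.

## Design choices where the design was open

- **Item-to-standard map of the star scheme.** The cumulative 5/7/9/11/14
  structure is fixed, but the assignment of items to the 14 standards is a
  package default, not a claim of fidelity to any deployed system:
  standards 1–5 are the demographic identifiers (name, ID number, age,
  gender code, location), 6–7 the clinical setting (pathological nature,
  at least one four-diagnosis finding), 8–14 the TCM content and its coded
  validity (symptom, symptom code valid, diagnosis, syndrome type coded
  validly, treatment, treatment code valid, dominant-disease code valid).
  The scheme is serialized inside the rule configuration and can be
  replaced wholesale.
- **13 coding rules over 12 code-bearing fields.** The four national TCM
  terminology standards are bound as: therapeutic methods → treatment
  codes, syndromes → syndrome type codes, diseases terminology → symptom
  codes, and the disease-and-Zheng classification → dominant-disease codes.
  The dominant-disease field therefore carries two rules (the
  administrative value set and the classification standard); both count
  toward k′ with equal weight, as no per-item weighting is defined. The
  fixture code sets for these two rules share identical entries so a
  single recorded code satisfies or violates both coherently.
- **Display rounding.** Half-up to whole points, applied only at display
  time (80.5 → 81). Internally all scores stay at full precision.
- **Batch star level.** The aggregation formula for a whole upload is
  implemented as the count-weighted mean of record star levels, rounded
  half-up — the simplest aggregate composed of the per-level counts. It is
  labelled a reconstruction in every report and is always accompanied by
  the full star distribution, so nothing is lost if a different aggregate
  is preferred downstream.
- **Duplicate record ids** are kept and flagged with a warning; upload
  batches are per-submission snapshots with no key constraint.

## Synthetic data generator

The generator emulates an upload batch with exact known ground truth. For
a target level L it satisfies every rule referenced by the standards in
L's prefix ("pinned"), and for L below the top level deliberately violates
one rule of the first standard beyond the prefix (choosing uniformly among
that standard's rules whose fields are not pinned). Items outside the
pinned prefix and the violation point are corrupted at configurable rates:
a field with no pinned rule may be blanked (`missingness`), and a present
code field whose coding rules are all unpinned may receive an out-of-range
code (`invalid_code_rate`) — a field whose presence is pinned but whose
code validity is not (e.g. gender) can still be miscoded. Star levels are
therefore exact by construction while the integrity and coding scores vary
with the rates.

The expected assessment is derived purely from the generator's own
field-level bookkeeping, never by running the assessment pipeline at
generation time, so the generate → assess round trip is a genuine
end-to-end check. Record content (names, ID numbers, terms, codes) comes
from invented fixture vocabularies; no real patient data and no official
standard codes appear anywhere. What passing tests therefore show is that
the engine scores *structured* records correctly under the configured
rules; they say nothing about upstream extraction of structure from
narrative clinical text, covariance between item defects in real records,
or the content of the real code tables, all of which are out of scope.

Default corruption rates in the acceptance run (missingness 0.1,
invalid-code rate 0.05) are placeholder magnitudes for a mostly-complete
hospital export; the realized star distribution is pinned exactly by the
per-level targets regardless of the rates.

## Numerical and degenerate-input conventions

- Exact rational arithmetic for batch scores; `decimal` half-up for
  display rounding and the batch star (no float `round` banker's ties).
- Empty batch: error in scoring, star aggregation, and the CLI (exit 2).
- Empty code set: rejected at load (a code range cannot be empty);
  duplicate codes collapse to the first occurrence with a warning.
- Malformed or negative age: field set missing, parse warning recorded;
  every input row is accounted for as a record and/or warnings, never
  silently dropped.
- Weights must sum to 1 within 1e-9; star thresholds must be strictly
  increasing with the top threshold equal to the number of standards.

## Problem sizes

The test suite exercises batches up to the full 28,348-record application
scale (a few seconds in pure Python) and sweeps smaller randomized batches
(n ≤ 50) against brute-force oracles: an independent record × rule recount
for the batch scores, and exhaustive/randomized prefix search for the star
level. `scripts/acceptance.py` regenerates the full-size batch from the
reference per-level star targets and reassesses it from the raw records.

## Known limitations

- No parsing of narrative Chinese clinical text; the engine consumes
  structured fields only.
- The default star scheme and the batch-star aggregate are documented
  reconstructions (see above), not recovered specifications.
- Real code tables must be supplied by the user; results obtained with
  the synthetic fixture sets characterize the engine, not any standard.
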
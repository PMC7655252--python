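# emrqc

Standard-compliance testing for batches of Traditional Chinese Medicine
(TCM) outpatient electronic medical records.

Hospital information platforms exchange outpatient EMR data whose value is
routinely undermined by two defects: mandatory items left blank, and coded
items (gender, ethnicity, TCM symptom/syndrome/treatment codes, …) filled
with values outside the ranges defined by the governing health information
standards — the WS 445.11-2014 administrative value sets and the national
TCM clinical terminology standards. `emrqc` is a configurable rules engine
that quantifies both defects for every upload batch, so data-quality teams
can give institutions concrete, per-record feedback before records enter a
shared platform.

## The model

For a batch of *n* records checked against *k* mandatory items and *k′*
coded items, with *Xᵢ* the number of blank mandatory items and *Yᵢ* the
number of noncompliant coded items in record *i*:

- **Integrity score** Sᵢ = (1 − ΣXᵢ / (n·k)) · 100
- **Coding score** S꜀ = (1 − ΣYᵢ / (n·k′)) · 100
- **Total score** Sₜ = w₁·Sᵢ + w₂·S꜀ with default weights 0.5 / 0.5

Scores are carried at full precision and rounded half-up to whole points
only for display (Sᵢ = 75 and S꜀ = 86 give Sₜ = 80.5, shown as **81**).

Each record is also graded **0–5 stars** against an ordered scheme of 14
standards with cumulative prefix thresholds 5/7/9/11/14: a record earns
level *L* only if the first threshold(*L*) standards all hold
simultaneously, and a record failing the one-star prefix is zero-star. The
defaults ship 16 mandatory rules, 13 coding rules, and a 14-standard
scheme; all three are plain configuration (YAML) and can be replaced
without code changes. The official standards' code tables are licensed
content and are not shipped — load real code tables as two-column
(code, term) TSV/CSV files; the package includes small synthetic fixture
code sets for testing and data generation.

A synthetic-batch generator constructs records backwards from target star
levels with controlled missingness and invalid-code rates, yielding exact
known ground truth for every score and star count.

## Worked example

```sh
cat > spec.yaml <<'EOF'
star_counts: {5: 3, 2: 2, 0: 1}
missingness: 0.2
invalid_code_rate: 0.1
EOF
emrqc gen --spec spec.yaml --seed 9 --out batch.csv --truth truth.json
emrqc validate batch.csv --out report.json --markdown report.md \
      --institution "Demo Clinic"
```

prints

```
wrote 6 synthetic records to batch.csv
assessed 6 records: integrity 89, coding 90, total 89, batch star 3
```

Six records were generated: three built to satisfy all 14 standards
(5-star), two satisfying exactly the first 7 (2-star), one violating the
1-star prefix (0-star), with star-irrelevant items randomly blanked (20 %)
or miscoded (10 %). Reassessing the CSV reproduces that distribution
exactly — `report.md` shows the star table 3/0/0/2/0/1 from five stars
down to zero — while the blanked and miscoded items pull the integrity and
coding scores down to 89 and 90 points. The batch star level (3) is the
count-weighted mean of the record star levels, rounded half-up; it is a
reconstruction and is always reported next to the full distribution.
`report.json` holds the same result losslessly, including full-precision
scores, per-record failed-item lists, and a fingerprint of the rule
configuration that produced it.

Library use mirrors the CLI:

```python
from emrqc import (BatchSpec, generate_batch, assess_batch,
                   default_rule_config, fixture_codeset_registry)

config = default_rule_config()          # 16 + 13 rules, 14 standards
registry = fixture_codeset_registry()   # synthetic code sets
batch = generate_batch(BatchSpec({5: 3, 2: 2, 0: 1}, 0.2, 0.1, seed=9),
                       config, registry)
report = assess_batch(batch.records, config, registry)
assert report.star_counts == batch.expected.star_counts
```

`emrqc rules --show-defaults` prints the complete default configuration;
`emrqc rules --write-fixture-codesets DIR` exports the fixture code sets.

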
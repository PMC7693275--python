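# taxonym

Fuzzy taxonomic name resolution for vascular-plant names against a
reference backbone, plus tooling to validate, summarize and diff
backbone tables and to generate synthetic test backbones with known
ground truth.

A backbone is a tab-delimited UTF-8 table mapping every published name
to a status (`accepted` / `synonym` / `unresolved`) and, for synonyms,
to its accepted name. Submitted names are standardized (whitespace,
hybrid `_x` markers, authority abbreviations, special-character
transliteration), decomposed into genus / epithet / infraspecific rank
and epithet / authority, and matched stage by stage with a configurable
Levenshtein budget per component. An exact hit at any stage preempts
fuzzy candidates, so verbatim names are never shadowed by typo-matches.

## Library quick start

```python
from taxonym import (
    MatchConfig, flatten_synonym_chains, load_reference, resolve_names,
)

table = flatten_synonym_chains(load_reference("backbone.tsv"))
results = resolve_names(["Hibiscus vitifolius", "Draba molissima"], table,
                        MatchConfig(max_distance_epithet=2))
for row in results:
    print(row.submitted_name, "->", row.matched_name, row.score)
```

Unresolvable names come back as rows that are empty except for the
submitted name and a `Score` diagnostic telling you which component
(genus, epithet, infraspecific epithet, authority) could not be matched.

## CLI

```sh
# resolve names (CSV to stdout or --out)
taxonym resolve --ref backbone.tsv "Hibiscus vitifolius" "Draba molissima"
taxonym resolve --ref backbone.tsv --names-file names.txt --out results.csv

# structural checks: dangling synonyms, synonym chains, cycles, duplicates
taxonym validate --ref backbone.tsv

# content counts (names, accepted species, hybrids, genera, families, ...)
taxonym summarize --ref backbone.tsv --format json

# compare two backbones
taxonym diff --ref-a old.tsv --ref-b new.tsv

# synthetic backbone with known ground truth
taxonym generate --out fixture.tsv --truth truth.csv --seed 1 \
    --n-genera 20 --synonym-fraction 0.3 --chain-fraction 0.2
```

Column headers and status vocabulary are configurable via `--dialect`:
built-in dialects `default` and `idiv` (dotted headers of the archived
catalogue export), or a `key = value` config file (see
`src/taxonym/data/dialect_default.conf`).

## Layout

| Module                | Purpose                                                     |
| --------------------- | ----------------------------------------------------------- |
| `taxonym.parser`      | name standardization, parsing, authority/orthography rules  |
| `taxonym.distance`    | Levenshtein edit distance (bounded scan variant)            |
| `taxonym.reference`   | backbone load/write, validation, chain flattening, summary, diff |
| `taxonym.matching`    | staged fuzzy resolution with per-component thresholds       |
| `taxonym.pipeline`    | batch resolution, CSV output schema                         |
| `taxonym.fixtures`    | synthetic backbones and corrupted queries with ground truth |
| `taxonym.cli`         | `taxonym` command-line entry point                          |
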
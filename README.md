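# carematch

Identify care-home addresses in routine population address data, and measure
how well each identification method works.

The package implements five index tests against a care-home registry —

- **flag** — an institution-flag code on the record (93 residential / 98 nursing),
- **exact** — exact match of the concatenated, normalized address,
- **postcode** — postcode match after removing spaces (missing postcodes are negative),
- **phonics** — a 0–100 score from Metaphone/Soundex overlap between the
  record and eligible care-home names, plus a postcode component,
- **markov** — a 0–100 naive-Bayes log-odds score over address words and
  adjacent word pairs, trained per health board against a known flag

— together with a full diagnostic-test-accuracy toolkit (confusion tables;
sensitivity/specificity/PPV/NPV with exact Clopper–Pearson intervals; ROC and
AUROC with Hanley–McNeil or DeLong-style Wald limits; researcher-constrained,
Youden and sensitivity=specificity cut-off selection; prevalence; a
sensitivity-driven sample-size formula) and a fully seeded synthetic data
generator that emulates the structure of real registers: address typos,
abbreviations, dropped lines, missing postcodes, private households sharing a
care-home postcode, historic (cancelled) care-home names, and an institution
flag with configurable sensitivity and false-positive rate.

## CLI

The pipeline is exposed as `carematch` with five subcommands
(exit codes: 0 ok, 2 config error, 3 data/alignment error):

```sh
# 1. generate a synthetic registry + population + truth labels
carematch simulate --preset tayside_over65 --out data/

# 2. train the markov score on the institution flag (or a truth CSV)
carematch train-markov --population data/population.csv --labels flag --out model.json

# 3. run all five methods
carematch match --registry data/registry.csv --population data/population.csv \
    --model model.json --out calls.csv

# 4. evaluate against the reference standard
carematch evaluate --calls calls.csv --truth data/truth.csv --out eval/

# 5. readable summary
carematch report --evaluation eval/
```

Presets (`fife_population`, `tayside_population`, `fife_over65`,
`tayside_over65`) fix the per-sample prevalence and institution-flag
operating characteristics; every stage is deterministic given the seed. A
YAML config file (`--config run.yaml`, per-command sections) can replace
flags; flags win on conflict.

## Library

```python
from carematch import (
    PRESETS, generate_registry, generate_sample,
    match_postcode, score_phonics, build_confusion, metric, auroc,
)

cfg = PRESETS["tayside_over65"]
registry = generate_registry(n_homes=40, board=cfg.board, seed=1)
sample = generate_sample(cfg, registry)
calls = {r.record_id: match_postcode(r, registry).positive for r in sample.records}
table = build_confusion(calls, sample.truth)
print(metric(table, "sensitivity").percent)
```

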
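# capl2

Batch scoring, interpretation and visualization for the Canadian Assessment
of Physical Literacy, 2nd edition (CAPL-2).

From 60 raw input variables per child (shuttle-run laps, plank hold,
agility-course trials, a pedometer week, questionnaire items and knowledge
answers), the package computes 40 derived variables: protocol scores, four
domain scores (physical competence /30, daily behaviour /30, motivation &
confidence /30, knowledge & understanding /10), an overall physical-literacy
score (0–100), age/gender-specific interpretive categories and per-domain
completeness statuses.

Design principles:

- **Quiet validation** — invalid or missing raw values never raise; they
  become missing markers that propagate through downstream scores, so a
  messy 10,000-row spreadsheet scores in one call.
- **Missing-component reweighting** — domain and overall scores with exactly
  one missing component are rescaled from the remaining components; two or
  more missing components yield a missing score. The daily behaviour domain
  is the exception and requires both parts.
- **Externalized tables** — every cut-point, bin table, validity bound and
  answer key lives in `src/capl2/data/default_config.yaml`; normative
  category thresholds live in `src/capl2/data/norms.csv`. Both can be
  overridden per run without code changes. Entries marked PROVISIONAL
  reconstruct manual-only tables (correct ranges and monotonicity, not
  transcriptions) — replace them with the official tables if you have the
  assessment manual.

## Python API

```python
import capl2

raw = capl2.generate_demo(n=500, seed=1)      # messy seeded demo data
scored = capl2.run_all(raw, sort="asis", seed=1)   # 500 x 100 table
capl2.export_table(scored, "scored.xlsx")

# individual helpers
capl2.validate_age("8.5")                     # -> 8
capl2.score_capl(20, None, 20, 5)             # -> 64.2857 (reweighted)
```

## Command line

```bash
# generate demo data
capl2 demo --n 500 --seed 1 --output demo.xlsx

# score a table (CSV or XLSX in/out; sort: asis | abc | zyx)
capl2 score --input demo.xlsx --output scored.csv --sort asis --seed 1 \
    [--config my_config.yaml] [--norms my_norms.csv]

# bar plot of mean scores per interpretive category
capl2 plot --input scored.csv --score pc_score \
    --interpretation pc_interpretation --output pc.png \
    [--colors "#daf7a6,#ffc300,#ff5733,#c70039"]
```

## Layout

- `src/capl2/validators.py` — quiet scalar validators (age, gender, scale
  items, clock times)
- `src/capl2/physical_competence.py` — shuttle run, plank, agility course,
  domain aggregation
- `src/capl2/daily_behaviour.py` — wear time, step validity, step averaging
  with seeded fourth-day imputation, domain score
- `src/capl2/questionnaires.py` — self-perception and exercise-regulation
  subscales, knowledge items, fill-in-the-blanks
- `src/capl2/interpretation.py` — overall score, normative category lookup,
  domain status
- `src/capl2/pipeline.py` — column scaffolding, full-table scoring, demo
  generator
- `src/capl2/io.py`, `src/capl2/plotting.py`, `src/capl2/cli.py` — table
  I/O, interpretation-grouped bar plots, CLI
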
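# shelftrial

Simulation and analysis pipeline for a five-arm randomised controlled
trial of **shelf positioning** and **front-of-pack labelling**
interventions in an online experimental supermarket, targeting the
healthiness and the environmental sustainability of food choices.

Online supermarkets decide the order in which products appear, and
almost all choices happen on the first page. The trial this package
models compares a control arm against four interventions — products
re-ordered to favour healthier items (health position), the same plus
visible A–E Nutri-Score-style labels (health position & labels), and
the analogous pair for environmental sustainability (eco position,
eco position & labels) — randomised 1:5:5:5:5. `shelftrial` provides
every computational stage as a tested library:

* **Product scoring** — the original FSAm-NPS (Nutri-Score)
  algorithm (threshold tables shipped as CSV data), its 0–100 scaling
  `(raw + 15)·100/55`, and A–E letters; plus a 0–100 composite eco
  score: the mean of four per-100 g environmental-indicator
  percentiles (GHG, water use, biodiversity loss, eutrophication),
  lettered by catalog quintile.
* **Positioning engine** — per-session uniform sort keys whose range
  depends on the product's letter (A: [1,2) … E: [1.4,6); control:
  [1,6) for all), ascending sort, pages of ≤ 28, and the decoy
  price-match label on a fixed random 10% of products.
* **Synthetic data** — a seedable foodDB-like catalog (~8400
  products, 10 shopping-list shelves + fillers) with real-world
  export quirks (decimal commas, "trace"/"nil"/"negligible", "<"
  prefixes, missing fields), and a configurable multinomial-logit
  shopper standing in for participants.
* **Pre-registered analysis** — primary OLS contrasts (health:
  identity scale at p < 0.025; eco: log-transformed with
  exponentiated effects), full-compliance / IQR-outlier /
  decimal-error sensitivity analyses, secondary nutrient and
  environmental models (p < 0.005), arm × covariate interactions,
  the Levene-branched price ANOVA (Welch + Games-Howell vs classic +
  Tukey), exploratory spill-over models, and the noncentral-t power
  calculation behind the 127 + 4 × 633 = 2659 design.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on
synthetic data (intermediates under `scratch/`, tables under
`results/`):

```bash
python analysis/01_generate_catalog.py   # --seed 42 by default
python analysis/02_score_products.py
python analysis/03_simulate_trial.py
python analysis/04_primary_analysis.py
python analysis/05_secondary_analysis.py
python analysis/06_power_analysis.py
```

With the default seed, `01` prints

```
generated 8400 products on 100 shelves; 8181 kept after removing 146
alcohol and 73 incomplete rows; 288 products carry comma decimals
```

— the completeness filter and the comma-decimal pathology at its
configured rate (binomially around 326/8400). `02` scores the
catalog (health letters A: 862 … E: 172; eco letters an even ~1636
per quintile by construction) and audits the comma bug: 46% of
corrupted products keep their letter once the decimals are fixed,
50% shift one letter, 4% two. `03` simulates 2659 participants and
applies the exclusion rules:

```
CONSORT flow: {'incomplete': 84, 'too_many_items': 0, 'speeder': 96,
               'too_few_categories': 311, 'included': 2168, 'total': 2659}
```

`04` fits the primary models on the 2168 analysed baskets:

```
dimension analysis       reference             comparison  estimate  ci_low  ci_high   p  significant
   health  primary         control        health_position    -2.670  -3.155   -2.185 0.0         True
   health  primary         control health_position_labels    -3.891  -4.378   -3.405 0.0         True
   health  primary health_position health_position_labels    -1.222  -1.501   -0.942 0.0         True
      eco  primary         control           eco_position     0.926   0.901    0.951 0.0         True
      eco  primary         control    eco_position_labels     0.900   0.877    0.924 0.0         True
      eco  primary    eco_position    eco_position_labels     0.972   0.958    0.988 0.0         True
```

Health estimates are differences in basket mean scaled Nutri-Score
(negative = healthier than control); eco estimates are exponentiated
multiplicative effects on the basket mean eco score (0.926 = a 7.4%
reduction). The synthetic shopper is calibrated for effect
*directions*, not magnitudes. `06` reproduces the design's sample
size exactly: f = 0.1 → 527 per group pairwise, 633 per intervention
group after 20% non-compliance inflation, control 127, total 2659.

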
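# Methods

`shelftrial` is a simulation-and-analysis pipeline for a five-arm
randomised trial of two choice-architecture interventions in an
online supermarket: **positioning** (ordering shelf listings so that
better-scoring products tend to appear earlier) and **labelling**
(displaying A–E front-of-pack grades), each targeted at either the
healthiness or the environmental sustainability of food choices.
This note records the models, parameter choices and numerical
conventions, and what the synthetic components do and do not emulate.

## Product scoring

### Health (FSAm-NPS / Nutri-Score)

Each product is scored with the original FSAm-NPS algorithm:
"negative" points for energy (kJ), total sugars, saturated fat and
sodium (0–10 each, threshold tables), minus "positive" points for
fruit/vegetable content, fibre and protein (0–5 each; fruit/veg up to
10 for beverages). Protein points are only subtracted when the
negative total is below 11 or the fruit/veg component is maximal;
cheese always counts protein; added fats replace the saturated-fat
lookup with the saturated-to-total-fat ratio. The raw score lies in
[−15, 40]; letters for general foods are A ≤ −1, B 0–2, C 3–10,
D 11–18, E ≥ 19. The threshold and cut-point tables ship as CSV data
files and the test suite checks the implementation against an
independently coded lookup oracle on 10⁴ random nutrient vectors.

Conventions worth stating:

* **0–100 scaling.** The "scaled" score is the affine map of the
  theoretical raw range, `(raw + 15) · 100/55`, which is
  catalog-independent and hits 0 and 100 exactly at the endpoints
  (higher = less healthy). A catalog min–max variant exists behind
  `scaling="minmax"` for sensitivity checks.
* **Energy units.** Catalogs record kcal; the points lookup converts
  to kJ at 4.184 kJ/kcal. Sodium is derived from salt at 400 mg/g.
* **Missing optional components** (fruit/veg, fibre, saturated fat)
  contribute 0 points with a logged warning, because catalog
  completeness is only enforced for energy/salt/sugar/fat. Missing
  *required* components raise.
* The trial simulation scores every synthetic product as a "general"
  food: alcohol is filtered out and the shopping list contains no
  beverages. The beverage/cheese/added-fat variants are implemented
  and tested but not exercised by the default trial.

### Eco score

Four per-100 g environmental indicators (GHG kg CO₂e,
scarcity-weighted water L, biodiversity loss species·10⁻¹⁴,
eutrophication g PO₄³⁻e) are each rank-transformed to an empirical
percentile within the catalog (midrank for ties: `(rank − 0.5)/n ·
100`), and the composite is their arithmetic mean; higher = less
sustainable. Letters are catalog quintiles of the composite (edges
at the 20/40/60/80th percentiles, type-7 quantiles), ties at an edge
going to the better letter. The percentile-mean aggregation is a
deliberate design choice where the source methodology is not
restated; it is isolated in one function (`eco_composite`) so an
alternative composite can be substituted without touching anything
else.

A structural consequence: a percentile-based composite has a
catalog-wide mean of 50 by construction, so *basket* means far below
50 require the shopping-list shelves to sit in the sustainable tail
of the whole catalog. The default generator gives filler shelves
much heavier environmental tails than target shelves, which pushes
simulated basket means to roughly 20–25 rather than the single-digit
values a strongly concentrated real catalog can produce. Relative
(multiplicative) arm effects — the quantities the analysis estimates
— are unaffected by this location difference.

## Synthetic catalog

`CatalogConfig.default()` builds ~8400 products: the ten
shopping-list shelves (sizes 56–120, so most paginate past the
28-per-page limit) plus 90 filler shelves. Per shelf, nutrients are
truncated normals with food-plausible means (e.g. cheese: 350 kcal,
28 g fat, 1.7 g salt; soup: 45 kcal, 0.55 g salt); energy, fat and
saturated fat share a latent factor so they correlate as in real
foods. Environmental indicators and price are log-normal
(right-skewed, strictly positive). `CatalogConfig.compact()` gives a
quirk-free 10 × 40 catalog for fast simulation studies.

Raw-data quirks are injected at configurable rates, with defaults
chosen to mirror the deposited data's pathology: per-product decimal
commas at 326/8400 (flagged in `comma_corrupted`), and per-field
"trace"/"nil"/"negligible" words, "<" prefixes and missing values at
1% each, plus a 2% alcohol flag. The **legacy parse mode** emulates
the upstream bug that produced wrong displayed labels: it truncates
at the decimal comma ("1,2" read as 1), which yields a letter-shift
distribution on corrupted products (mostly unchanged or one letter
off) matching the pattern of the study's audit; the corrected parser
converts the comma and recovers the true value.

### Nutrient-string recoding

Rule order is fixed as: comma fix → trace-word recode → "<" strip →
small-value thresholds (fat/sugar < 0.5 g → 0; salt < 0.01 g → 0; a
"<"-prefixed salt value ≥ 0.01 keeps its numeric part). The "<" rule
is stated in the source protocol only for salt; fat and sugar are
treated analogously (strip, then the 0.5 rule) as the least
surprising completion. Unparseable strings become NaN — never a
silent zero — and the catalog completeness filter removes such rows.

## Positioning engine

Control: every product draws a sort key uniformly from [1, 6).
Intervention arms: A [1, 2), B [1.1, 3), C [1.2, 4), D [1.3, 5),
E [1.4, 6), on the targeted dimension's letter; shelves sort
ascending (ties broken by product id) and paginate into pages of at
most 28. Endpoints are half-open — a measure-zero deviation from
"between". The implied stochastic ordering is strong:
P(key_A < key_E) = 0.96087 by closed-form integration, and all ten
letter-pair probabilities are verified against Monte Carlo. Keys are
drawn **fresh per shopping session** (one frozen ordering per arm is
the config alternative); the source protocol does not state which was
used, and per-session draws avoid a single frozen ordering driving
every simulated result. A fixed random 10% of products carry the
decoy price-match label, identical across arms for a given seed.

## Synthetic shopper

The shopper is invented plumbing — the study measured people — and
all of its parameters are exposed:

| parameter | default | meaning |
|---|---|---|
| `tau` | 10 | position-sensitivity scale; utility −rank/τ |
| `beta_label` | 0.3 | utility per visible grade step (A=+2 … E=−2) |
| `beta_price` | 0.05 | utility per GBP |
| `p_skip` (adherent / non-adherent) | 0.02 / 0.45 | per-category skip probability |
| `nonadherent_fraction` | 0.2 | matches the design's assumed 20% non-compliance |
| `extra_item_rate` | 0.15 | Poisson mean of off-list additions |
| `dropout_rate` | 0.03 | sessions never completed |
| `speeder_fraction` / factor | 0.04 / 0.2 | fast-completion subpopulation |
| completion time | log-normal, median 480 s, σ = 0.5 | |

Choice is multinomial logit via Gumbel-max over the displayed shelf;
`tau = inf` with zero betas is exactly uniform (the "null shopper"
used for calibration). With τ = 10 and ~100-product shelves, page-1
items dominate selection, consistent with the observation that online
grocery choices are made almost entirely on the first page — the
mechanism the positioning intervention exploits. Defaults were set so
that arm effects have the directions the trial reports (health arms
lower basket Nutri-Score; eco arms lower basket eco score; label arms
slightly stronger than position-only); magnitudes are not calibrated
to the human data and should not be read as predictions.

Baskets below the 10-item checkout minimum (after skips) are filled
from randomly chosen shelves, since a basket that cannot check out
would never reach analysis; the 15-item maximum is enforced. The
exclusion rules — incomplete, > 20 products, completion under 30% of
the median time of completed sessions, < 7 covered categories — are
attributed to the first failing rule in that order, so the
CONSORT-style counts always sum to the total.

Participant demographics (gender, age band, education, income) and
the three meat/dairy frequency answers are sampled from marginals
matching the study sample's printed distribution. The
meat-consumption score sums three 0–5 frequency answers and bands
them low 0–5 / medium 6–10 / high 11–15; an alternative 0–4 scheme
with bands 0–4 / 5–8 / 9–12 (the two appear inconsistently in the
source report) is available via `scheme="table2"`.

## Statistical pipeline

* **Primary models** (threshold p < 0.025): OLS arm contrasts with
  control as reference, plus a separate position-referenced model for
  the add-on-labels contrast. The health outcome (basket mean scaled
  Nutri-Score) is untransformed; the eco outcome is natural-log
  transformed and estimates/CIs are exponentiated to multiplicative
  effects. Non-positive eco outcomes raise, naming the basket.
* **Sensitivity analyses**: full-compliance subsample (exactly one
  product per category, nothing else); the 1.5-IQR outlier rule with
  type-7 quartiles and inclusive bounds; and the decimal-error
  re-analyses (drop selected corrupted products; drop their
  purchasers in the position-&-labels arm).
* **Secondary models** (p < 0.005): energy density, salt, fat, sugar
  (identity); GHG, water, biodiversity, eutrophication (logged +
  exponentiated).
* **Interactions** (p < 0.005): arm × covariate OLS for gender, age
  group, education, income and meat level; "other gender identity"
  and income "prefer not to say" rows are dropped and the lowest
  education band merged upward, mirroring the study's handling of
  small cells.
* **Price** (pairwise p < 0.025): Levene's test (median-centred)
  decides the branch — Welch ANOVA + Games-Howell when p < 0.05,
  classic ANOVA + Tukey HSD otherwise.
* **Spill-over** (exploratory, no threshold): health arms on the eco
  outcome (log + exp) and eco arms on the Nutri-Score outcome.
* CIs are non-robust normal-theory OLS CIs at 95%. Thresholds are
  fixed pre-registered cutoffs, not p-value adjustments.

### Power calculation

The pairwise group size comes from the noncentral-t two-sample
computation at d = 2f, two-sided α = 0.05, power 0.9 (f = 0.1 →
527/group). Non-compliance inflation defaults to multiplication by
(1 + rate) — ceil(527 × 1.2) = 633 — because that convention, with
the control group at 1/5 of an intervention group (127), reproduces
the published design total 127 + 4 × 633 = 2659 exactly; division by
(1 − rate) is available as `inflation="divide"`. All roundings are
upward.

## Calibration experiments

Two standing checks validate the pipeline end to end
(`shelftrial.validation`):

* **Null calibration**: 1000 replicate trials of 210 participants
  with the uniform shopper, each pushed through simulate → exclusions
  → primary fit; the position-vs-control rejection rate at 0.025 must
  stay inside the binomial 99% band. Replicates use a compact
  10 × 40-product catalog, which keeps the experiment to about two
  minutes without changing what is being tested.
* **Effect recovery**: a 0.76× multiplicative shift planted on a
  log-normal eco outcome (σ_log = 0.45, matching the coefficient of
  variation of the reported basket scores) at 500/arm over 200
  replicates is recovered with |bias| < 0.02 after exponentiation.

## What the synthetic data does not show

Passing tests demonstrate that the scoring, positioning, simulation
and analysis machinery is correct and calibrated — not that the
synthetic shopper reproduces human effect magnitudes. In particular:
basket eco-score *levels* sit higher than a concentrated real catalog
would produce (see above); the shopper has no brand loyalty, search
behaviour, or within-person correlation across categories; label
effects are linear in grade steps; and survey-derived constructs
(acceptability, consciousness scales) are out of scope. The
decimal-error emulation reproduces the *mechanism* (wrong displayed
letters traceable to comma decimals) and the rough shape of the
letter-shift audit, not its exact distribution.
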
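# Methods

## Scope and data model

The pipeline analyzes spontaneous adverse-event reports in the JADER
four-table shape: DEMO (one row per case: sex, age band, weight band),
DRUG (one row per drug per case, with an involvement code among
"suspected", "concomitant", "interaction"), REAC (one row per reported
reaction as a MedDRA preferred term), and optionally HIST (underlying
disease; parsed, never used). Tables are joined in memory into one
record per distinct case id; orphan cases (present in only one table)
are kept, and the join conserves every child row.

Only suspected-drug records enter the analysis. Adverse events are
classified by a curated catalog of 125 preferred terms in 21 irAE
categories; the catalog is a closed list — no MedDRA hierarchy
traversal — and PT matching is string-exact after canonicalization
(case, whitespace, typographic apostrophes and dashes). American and
British spellings ("Diarrhea", "Diarrhoea haemorrhagic") are distinct
catalog rows, exactly as listed, never fuzzy-matched. Category order is
fixed everywhere to the packaged matrix's row order, because feature
order is tie-break-relevant downstream.

## Counting and ratios

The counting unit is the distinct case, deduplicated at every
aggregation level: a case contributes at most once to a (drug, PT)
cell, once to a (drug, category) cell, and once per drug to the
per-drug irAE and all-reaction counts. Totals ("all drugs") count cases
with at least one suspected drug of any name, roster or not.

The category share matrix divides each drug's category case count by
the **all-drug** category total. This denominator choice is the only
one consistent with the packaged tables: cells like 67.4% are
impossible against per-drug denominators given the per-drug totals, and
category rows summing above 100% arise naturally from co-suspected
combination regimens (nivolumab+ipilimumab, durvalumab+tremelimumab).
The per-PT table's "case" column counts cases with *any* roster drug
suspected — a union, not the per-drug sum, so it is computed during
counting (it cannot be recovered from per-drug counts once drugs are
co-suspected).

Percentages are kept at full precision internally; displayed values are
rounded half-up to one decimal (all 133 packaged published cells
reproduce under this convention). Zero denominators yield 0 with a
machine-parseable warning, never NaN.

## Synthetic-report generator

The generator emulates the structural features of a real extract that
the counting stage depends on: case-linked rows across three tables,
involvement codes, several reactions per case, co-suspected drug pairs,
concomitant (non-contributing) drug rows, and non-irAE background
reactions. Per case: co-suspect pairs fire first (jointly marking both
drugs suspected), remaining drugs are independent Bernoulli draws, each
suspected drug triggers its preferred terms independently, and a case
with no reaction draws one background term, so every case carries at
least one reaction. Ground truth is tallied during generation with the
same distinct-case semantics as the counting stage and stored in the
same container, making extraction correctness an exact integer
equality — verified over randomized configurations.

It deliberately does **not** model reporting dynamics over time,
stimulated reporting, under-reporting, duplicate case versions across
quarterly releases, or demographic structure; passing tests therefore
certify the pipeline's arithmetic and algorithms, not robustness to
those real-world biases.

Presets (fixed once, with seeds mandatory):

* `separable4` — four well-separated profile clusters of sizes 1/2/1/4
  (matching the published unit-composition sizes), signature categories
  per cluster at trigger probability 0.5, faint 0.02 off-cluster noise,
  4000 cases. Used for cluster-recovery tests.
* `table3like` — drug marginals proportional to the published per-drug
  report volumes relative to the full database (≈881k reports), one
  representative PT per category with trigger probability ∝ target
  share / marginal (base incidence 0.02), two co-suspect pairs at
  plausible combination rates, 30,000 cases. Its own expectation is
  computed exactly by enumerating the suspected-set distribution, and
  simulations are checked against that expectation within binomial
  error; it *approximates* the published matrix rather than matching it
  (shares renormalize through the union denominator).
* `nullflat` — exchangeable drugs, the negative control. With data
  re-simulated per replicate, no partition reaches 0.5 frequency (in
  practice nearly every replicate yields a different partition).

## Self-organizing map

Online Kohonen training on a rectangular grid: per step, the
best-matching unit (BMU) by Euclidean distance (ties to the lowest
row-major unit index) and all units within the decayed neighborhood
move toward the input. Learning rate α(t) = α₀(1 − t/T) and radius
r(t) = r₀(1 − t/T) decay linearly; the bubble kernel updates units
within Chebyshev grid distance r(t) with weight 1, the Gaussian kernel
uses exp(−d²/2r²) with r floored at 0.01 to stay finite. Inputs are
presented in a seeded random order reshuffled each epoch.

Defaults: 6×1 grid, T = 100 × n rows, α₀ = 0.05, r₀ = ⌈max(grid
dims)/2⌉, bubble, sample initialization (data rows drawn with
replacement), features unscaled — category shares are already
commensurate percentages — with an optional z-scaling flag. The larger
map configuration is 5×5 = 25 units; at PT level the input is the
125-feature PT-share matrix (same share semantics at PT granularity).

Because training is stochastic, partitions (label-invariant sets of
unit-sharing drug groups) are stabilized as the mode over many seeds.
Quantization error (mean input-to-BMU distance) is reported as the fit
diagnostic, and adjacent-unit weight distances are exported as a text
U-matrix surrogate in place of a rendered map.

### Known limitation: the published grouping is not the Euclidean mode

On the packaged 8×21 matrix, the modal 6×1 partition over 100 seeds is
{atezolizumab}, {avelumab, cemiplimab, durvalumab, tremelimumab},
{ipilimumab, nivolumab}, {pembrolizumab} — not the published
{ipilimumab, pembrolizumab} / {nivolumab} split. The cause is geometric,
not numeric: on raw percentage shares ipilimumab is closer to nivolumab
(Euclidean distance 38.8) than to pembrolizumab (48.3), dominated by
the hypopituitarism and adrenal-insufficiency columns. Z-scaling the
features reverses that (2.97 vs 4.60) and recovers {ipilimumab,
pembrolizumab} — but then durvalumab separates from the low-volume
quartet. No configuration surveyed (scaling on/off × bubble/Gaussian ×
training length × initial radius, 60 seeds each) produced the published
partition even once, so the published assignment likely reflects a
different training schedule or normalization in the original toolchain,
or a single stochastic run rather than a mode. The corresponding
acceptance test asserts the published partition and is expected to
fail; it is kept failing rather than weakened, and the disagreement is
confined to ipilimumab/pembrolizumab/nivolumab/durvalumab placement —
the low-volume quartet and atezolizumab's isolation are stable across
all settings. The downstream tree does not depend on this: it is grown
from the published unit labels.

## Classification tree

Standard CART with Gini impurity. Thresholds are midpoints of adjacent
distinct observed values; rows with value < threshold go left. Splits
maximize the weighted impurity decrease and must decrease impurity
strictly; exact ties resolve by feature order — default: the *last*
tying feature in the fixed category order, then the smallest
threshold — and the alternative (first-feature) is exposed. On the
packaged matrix many categories separate the low-volume quartet
perfectly; the last-feature rule selects Type 1 diabetes mellitus at
2.55 and likewise at the atezolizumab/nivolumab node (17.1), while the
hematological-disorder split (1.2) is unique. The first-feature rule
yields the same partition via Adrenal insufficiency — the partition,
not the variable identity, is the stable object.

Defaults allow single-row leaves (min_split = 2, min_bucket = 1, no
pruning): with eight labeled rows and a descriptive goal, forest-scale
guardrails would refuse to split at all. Rules are rendered one per
leaf with full-precision thresholds plus a half-up one-decimal display
form.

## Numerical conventions and degenerate inputs

* Half-up display rounding via decimal arithmetic, with an 1e-8
  pre-snap so binary-float midpoints (2.549999…98) round as their
  decimal value (2.55 → 2.6).
* Impurity-decrease ties use an absolute 1e-12 epsilon.
* Empty inputs fail fast: empty catalogs, empty data matrices, all-zero
  class counts, and degenerate generator configs (no suspected drug
  possible) raise before any computation.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical config + seed reproduces
  byte-identical artifacts.

## Problem sizes used by the test and acceptance runs

Cluster-recovery and negative-control checks use 2000–4000 simulated
cases and 20–50 training seeds; generator-vs-expectation checks use
60,000 cases; the published-matrix analyses are 8×21 throughout. The
full suite runs in well under a minute on one CPU; the acceptance
script is sub-second.
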
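# irae-som

Profiling immune checkpoint inhibitors (ICIs) by their immune-related
adverse-event (irAE) reports: a reusable pipeline for spontaneous-report
databases in the shape of JADER (the Japanese Adverse Drug Event Report
database), covering report parsing, case counting, reporting-ratio
matrices, self-organizing-map (SOM) clustering of drug profiles, and
decision-tree extraction of human-readable screening rules.

It is written for pharmacovigilance analysts and biostatisticians who
want the whole chain — from raw DEMO/DRUG/REAC tables to "which single
adverse-event categories discriminate the drug groups" — as tested,
scriptable Python rather than a one-off database workflow.

## Method

**Counting.** The unit of analysis is the case (one spontaneous report).
Only drug records with involvement "suspected" count. A curated catalog
maps 125 MedDRA preferred terms (PTs) to 21 irAE categories. For drug
*d* and category *c*, let *n(d,c)* be the number of distinct cases with
*d* suspected and at least one PT of *c* reported, and *n(c)* the same
count over **all** suspected drugs. Three ratio tables follow:

* per drug: RR(d) = 100 · (irAE cases of *d*) / (all-reaction cases of *d*);
* per PT: RR(p) = 100 · (cases with any roster drug suspected) / (all-drug cases);
* per category: **RR(d,c) = 100 · n(d,c) / n(c)** — the drug's share of
  the category total. Because combination regimens co-suspect several
  drugs on one case, the shares of a category may sum above 100%.

**SOM.** The 8 drug profile vectors (rows of the 8×21 share matrix) are
clustered by Kohonen competitive learning on a rectangular grid: at step
*t* the best-matching unit *b(x)* = argmin‖w<sub>u</sub> − x‖ and its
grid neighbors move by w<sub>u</sub> ← w<sub>u</sub> + α(t)·h(u,b,t)·(x −
w<sub>u</sub>), with α and the neighborhood radius decaying linearly.
Drugs sharing a unit after training share an irAE profile; training is
stochastic, so partitions are stabilized as the mode over many seeds.

**CART.** A Gini classification tree grown on the same matrix with the
SOM unit numbers as labels turns the clustering into screening rules:
splits are midpoints of adjacent observed values, chosen to maximize the
weighted impurity decrease 𝐺(parent) − Σ (n<sub>child</sub>/n)·𝐺(child),
𝐺 = 1 − Σ p<sub>k</sub>².

The published summary tables (per-PT and per-drug counts, the 8×21 share
matrix, the published unit assignment) ship as packaged data, because
the underlying database snapshot cannot be re-downloaded reproducibly.
A synthetic-report generator with exact ground-truth counts makes every
stage testable end to end.

## Worked example

```python
from irae_som import extract_rules, grow, load_category_matrix, load_unit_labels

matrix = load_category_matrix()          # 8 drugs x 21 irAE categories, percent
units = load_unit_labels()               # published 6x1 SOM unit per drug
tree = grow(matrix, [units[d] for d in matrix.drugs])
for rule in extract_rules(tree):
    print(rule)
```

prints

```
IF Type 1 diabetes mellitus < 2.55 (display 2.6) THEN unit 5 (Avelumab, Cemiplimab, Durvalumab, Tremelimumab)
IF Type 1 diabetes mellitus >= 2.55 (display 2.6) AND Hematological disorder < 1.2000000000000002 (display 1.2) THEN unit 3 (Ipilimumab, Pembrolizumab)
IF Type 1 diabetes mellitus >= 2.55 (display 2.6) AND Hematological disorder >= 1.2000000000000002 (display 1.2) AND Type 1 diabetes mellitus < 17.099999999999998 (display 17.1) THEN unit 4 (Atezolizumab)
IF Type 1 diabetes mellitus >= 2.55 (display 2.6) AND Hematological disorder >= 1.2000000000000002 (display 1.2) AND Type 1 diabetes mellitus >= 17.099999999999998 (display 17.1) THEN unit 2 (Nivolumab)
```

Reading: a drug whose type 1 diabetes mellitus share of all-drug
category cases is below 2.6% belongs to the low-report-volume group
(avelumab, cemiplimab, durvalumab, tremelimumab); among the rest, a
hematological-disorder share below 1.2% marks ipilimumab/pembrolizumab,
and the 17% diabetes threshold separates nivolumab from atezolizumab.

More in `examples/` (one script per capability: simulation and
counting, ratio arithmetic, SOM clustering, rule extraction, the full
pipeline) and via the CLI:

```bash
irae-som tree                 # rules on the packaged matrix
irae-som simulate --preset separable4 --seed 1 --outdir out/
irae-som run --mode matrix-fixture --seed 1 --outdir run/
irae-som report run/
```

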
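"""Synthetic spontaneous-report generator with exact ground-truth counts.

Emulates the structure of a JADER extract — case-linked DEMO/DRUG/REAC
rows, "suspected"/"concomitant" involvement codes, several reactions per
case, and co-suspected drug combinations — so that every downstream stage
is testable without a database download.  It deliberately does *not*
model reporting dynamics: no time trends, stimulated reporting, or
under-reporting, which are the structural biases of real spontaneous
reporting systems.

Sampling model, per case:

1. co-suspect couplings first: each configured drug pair is jointly
   marked suspected with its pair probability;
2. remaining drugs are independent Bernoulli draws on their marginals;
3. each suspected drug triggers each of its preferred terms
   independently with the configured probability; a case with no
   reaction draws one background (non-irAE) term instead, and a
   background term is appended with ``background_rate`` otherwise, so
   the irAE-case vs all-reaction-case distinction is exercised;
4. with ``concomitant_rate`` a non-suspect drug row is added.

Ground truth is tallied during generation with the same distinct-case
semantics the counting stage documents, into the same ``CountTables``
container, so extraction correctness is a direct equality check.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .catalog import IraeCatalog, load_catalog
from .jader_io import (DemoRecord, DrugRecord, Involvement, JaderTables,
                       ReacRecord)
from .tables import CountTables, RatioMatrix

__all__ = ["SimConfig", "simulate", "preset_profiles", "expected_ratio_matrix"]

BACKGROUND_PTS = ["Headache", "Nausea", "Pyrexia", "Fatigue", "Decreased appetite"]

_AGE_BANDS = ["20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80-89"]


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; every probability lies in [0, 1]."""

    n_cases: int
    drugs: tuple  # ((drug_name, marginal suspected probability), ...)
    pt_probs: dict  # drug -> {pt_name: per-case trigger probability}
    co_suspect: tuple = ()  # (((drug_a, drug_b), joint probability), ...)
    concomitant_rate: float = 0.0
    background_rate: float = 0.0
    background_pts: tuple = tuple(BACKGROUND_PTS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        if not self.drugs:
            raise ValueError("at least one drug is required")
        probs = [p for _, p in self.drugs]
        probs += [p for _, p in self.co_suspect]
        probs += [self.concomitant_rate, self.background_rate]
        probs += [q for d in self.pt_probs.values() for q in d.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        names = {d for d, _ in self.drugs}
        for (a, b), _ in self.co_suspect:
            if a not in names or b not in names:
                raise ValueError(f"co_suspect pair ({a!r}, {b!r}) not in the drug list")
        if all(p == 0 for _, p in self.drugs) and all(p == 0 for _, p in self.co_suspect):
            raise ValueError("degenerate config: no suspected drug can ever be sampled")
        if not self.background_pts and (
            self.background_rate > 0
            or any(all(q == 0 for q in d.values()) or not d for d in self.pt_probs.values())
        ):
            raise ValueError("background_pts must be non-empty when background draws are possible")

    @property
    def drug_names(self) -> list[str]:
        return [d for d, _ in self.drugs]


def simulate(
    config: SimConfig,
    catalog: Optional[IraeCatalog] = None,
) -> tuple[JaderTables, CountTables]:
    """Generate report tables and the exactly-matching ground-truth counts.

    Identical config + seed gives byte-identical tables.  The catalog
    (default: packaged) maps sampled PTs to categories for the
    category-level ground truth.
    """
    catalog = catalog if catalog is not None else load_catalog()
    rng = np.random.default_rng(config.seed)
    roster = config.drug_names
    demo: list[DemoRecord] = []
    drug_rows: list[DrugRecord] = []
    reac_rows: list[ReacRecord] = []
    gt = CountTables(roster=list(roster))

    for i in range(config.n_cases):
        cid = f"C{i + 1:07d}"
        suspected: dict[str, None] = {}
        for (a, b), p in config.co_suspect:
            if rng.random() < p:
                suspected.setdefault(a)
                suspected.setdefault(b)
        for d, p in config.drugs:
            if d not in suspected and rng.random() < p:
                suspected.setdefault(d)

        pts: dict[str, None] = {}
        for d in suspected:
            for pt, q in config.pt_probs.get(d, {}).items():
                if rng.random() < q:
                    pts.setdefault(pt)
        if config.background_rate and rng.random() < config.background_rate:
            pts.setdefault(str(rng.choice(config.background_pts)))
        if not pts:
            pts.setdefault(str(rng.choice(config.background_pts)))

        demo.append(DemoRecord(cid,
                               sex=("female" if rng.random() < 0.5 else "male"),
                               age_band=str(rng.choice(_AGE_BANDS))))
        for d in suspected:
            drug_rows.append(DrugRecord(cid, d, Involvement.SUSPECTED))
        if config.concomitant_rate and rng.random() < config.concomitant_rate:
            spare = [d for d in roster if d not in suspected] or roster
            drug_rows.append(DrugRecord(cid, str(rng.choice(spare)),
                                        Involvement.CONCOMITANT))
        for pt in pts:
            reac_rows.append(ReacRecord(cid, pt))

        # ground-truth tally: same distinct-case semantics as the counting stage
        if suspected:
            irae_pts = [p for p in pts if p in catalog]
            cats: dict[str, None] = {}
            for p in irae_pts:
                cats.setdefault(catalog.category_of(p))
            for p in irae_pts:
                gt.n_pt_total[p] += 1
                gt.n_pt_roster[p] += 1
            for c in cats:
                gt.n_cat_total[c] += 1
                gt.n_cat_roster[c] += 1
            for d in suspected:
                gt.n_drug_all[d] += 1
                if irae_pts:
                    gt.n_drug_irae[d] += 1
                for p in irae_pts:
                    gt.n_drug_pt[d, p] += 1
                for c in cats:
                    gt.n_drug_cat[d, c] += 1

    return JaderTables(demo, drug_rows, reac_rows), gt


def ground_truth_to_json(gt: CountTables, path) -> None:
    """Serialize ground-truth counts alongside the generated tables."""
    def enc(c):
        return {("|".join(k) if isinstance(k, tuple) else k): v for k, v in c.items()}
    payload = {
        "roster": gt.roster,
        "n_drug_pt": enc(gt.n_drug_pt), "n_pt_total": enc(gt.n_pt_total),
        "n_drug_cat": enc(gt.n_drug_cat), "n_cat_total": enc(gt.n_cat_total),
        "n_drug_irae": enc(gt.n_drug_irae), "n_drug_all": enc(gt.n_drug_all),
        "n_pt_roster": enc(gt.n_pt_roster), "n_cat_roster": enc(gt.n_cat_roster),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# presets

ICI_DRUGS = [
    "Atezolizumab", "Avelumab", "Cemiplimab", "Durvalumab",
    "Ipilimumab", "Nivolumab", "Pembrolizumab", "Tremelimumab",
]

#: Generating partition of the ``separable4`` preset: one high-volume
#: profile, one mid pair, one distinct single, and a four-drug low-volume
#: group, mirroring the published unit composition sizes (1, 2, 1, 4).
SEPARABLE4_PARTITION = (
    ("Nivolumab",),
    ("Ipilimumab", "Pembrolizumab"),
    ("Atezolizumab",),
    ("Avelumab", "Cemiplimab", "Durvalumab", "Tremelimumab"),
)

# signature categories per cluster; one representative PT per category
_CLUSTER_SIGNATURES = {
    0: ["Adrenal insufficiency", "Hypopituitarism", "Type 1 diabetes mellitus",
        "Hyperthyroidism", "Thyroid dysfunction"],
    1: ["Colitis", "Hepatitis", "Rash", "Gastritis", "Eye disease"],
    2: ["Encephalitis/Meningitis", "Pneumonitis", "Neurological disorder",
        "Nephritis/renal dysfunction"],
    3: ["Hematological disorder", "Hemophagocytic syndrome", "Myocarditis",
        "Myositis/Rhabdomyolysis"],
}

# published per-drug all-reaction case volumes, used as marginal weights
_DRUG_VOLUME = {
    "Atezolizumab": 6692, "Avelumab": 597, "Cemiplimab": 31, "Durvalumab": 3568,
    "Ipilimumab": 12016, "Nivolumab": 22944, "Pembrolizumab": 17380,
    "Tremelimumab": 298,
}
_TOTAL_REPORTS = 880_999  # all-cause report volume the drug marginals refer to


def _rep_pt(catalog: IraeCatalog, category: str) -> str:
    return catalog.members(category)[0]


def preset_profiles(name: str, catalog: Optional[IraeCatalog] = None) -> SimConfig:
    """Documented generator presets.

    * ``separable4`` — four well-separated profile clusters of sizes
      1/2/1/4; signature categories per cluster with low cross-cluster
      noise, so the generating partition is recoverable by clustering.
    * ``table3like`` — drug marginals proportional to the published
      per-drug report volumes and per-category trigger probabilities
      chosen so the expected share matrix approximates the published
      one, including two co-suspected combination pairs.
    * ``nullflat`` — exchangeable drugs (identical trigger profiles), the
      negative control: no partition should dominate.
    """
    catalog = catalog if catalog is not None else load_catalog()
    if name == "nullflat":
        pts = {c: _rep_pt(catalog, c) for c in catalog.categories[:6]}
        shared = {pt: 0.15 for pt in pts.values()}
        return SimConfig(
            n_cases=2000,
            drugs=tuple((d, 0.25) for d in ICI_DRUGS),
            pt_probs={d: dict(shared) for d in ICI_DRUGS},
            concomitant_rate=0.1,
            background_rate=0.2,
            seed=0,
        )
    if name == "separable4":
        cluster_of = {d: k for k, group in enumerate(SEPARABLE4_PARTITION) for d in group}
        pt_probs = {}
        for d in ICI_DRUGS:
            sig = _CLUSTER_SIGNATURES[cluster_of[d]]
            probs = {_rep_pt(catalog, c): 0.5 for c in sig}
            # faint off-cluster noise keeps rows from being exactly axis-aligned
            for c in catalog.categories[:2]:
                probs.setdefault(_rep_pt(catalog, c), 0.02)
            pt_probs[d] = probs
        return SimConfig(
            n_cases=4000,
            drugs=tuple((d, 0.25) for d in ICI_DRUGS),
            pt_probs=pt_probs,
            concomitant_rate=0.1,
            background_rate=0.2,
            seed=0,
        )
    if name == "table3like":
        from .fixtures import load_category_matrix

        target = load_category_matrix()
        marginals = {d: _DRUG_VOLUME[d] / _TOTAL_REPORTS for d in ICI_DRUGS}
        base = 0.02  # overall per-case category incidence scale
        pt_probs: dict[str, dict[str, float]] = {d: {} for d in ICI_DRUGS}
        for j, c in enumerate(target.features):
            pt = _rep_pt(catalog, c)
            for i, d in enumerate(target.drugs):
                share = target.values[i, j] / 100.0
                if share <= 0:
                    continue
                q = min(1.0, base * share / marginals[d])
                pt_probs[d][pt] = q
        return SimConfig(
            n_cases=30_000,
            drugs=tuple((d, marginals[d]) for d in ICI_DRUGS),
            pt_probs=pt_probs,
            co_suspect=((("Nivolumab", "Ipilimumab"), 0.004),
                        (("Durvalumab", "Tremelimumab"), 0.0008)),
            concomitant_rate=0.15,
            background_rate=0.3,
            seed=0,
        )
    raise ValueError(f"unknown preset {name!r}")


def expected_ratio_matrix(
    config: SimConfig,
    catalog: Optional[IraeCatalog] = None,
) -> RatioMatrix:
    """Analytic expected drug x category share matrix of a generator config.

    Enumerates the joint distribution of the suspected-drug set exactly
    (co-suspect couplings first, then independent marginals) and, for each
    set, the probability that at least one preferred term of the category
    fires.  The returned cell is
    ``100 * E[n_drug_cat] / E[n_cat_total]`` — the large-sample limit of
    the simulated share.  Exponential in the number of drugs; guarded to
    small rosters.
    """
    catalog = catalog if catalog is not None else load_catalog()
    drugs = config.drug_names
    if len(drugs) > 12 or len(config.co_suspect) > 8:
        raise ValueError("exact enumeration is limited to small configurations")
    cats = list(catalog.categories)
    pts_of = {c: set(catalog.members(c)) for c in cats}

    # probability of each suspected-drug set
    set_prob: dict[frozenset, float] = {}
    pair_list = list(config.co_suspect)
    for pair_bits in itertools.product([0, 1], repeat=len(pair_list)):
        p_pairs = 1.0
        forced: set[str] = set()
        for bit, ((a, b), p) in zip(pair_bits, pair_list):
            p_pairs *= p if bit else (1.0 - p)
            if bit:
                forced |= {a, b}
        free = [(d, p) for d, p in config.drugs if d not in forced]
        for free_bits in itertools.product([0, 1], repeat=len(free)):
            prob = p_pairs
            S = set(forced)
            for bit, (d, p) in zip(free_bits, free):
                prob *= p if bit else (1.0 - p)
                if bit:
                    S.add(d)
            if prob > 0:
                key = frozenset(S)
                set_prob[key] = set_prob.get(key, 0.0) + prob

    num = np.zeros((len(drugs), len(cats)))
    den = np.zeros(len(cats))
    for S, pS in set_prob.items():
        if not S:
            continue
        for j, c in enumerate(cats):
            p_none = 1.0
            for d in S:
                for pt, q in config.pt_probs.get(d, {}).items():
                    if pt in pts_of[c]:
                        p_none *= 1.0 - q
            p_any = 1.0 - p_none
            if p_any <= 0:
                continue
            den[j] += pS * p_any
            for i, d in enumerate(drugs):
                if d in S:
                    num[i, j] += pS * p_any
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, 100.0 * num / den, 0.0)
    return RatioMatrix(list(drugs), cats, vals)
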
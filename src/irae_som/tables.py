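"""Case counting and reporting-ratio tables.

Counting semantics
------------------
The counting unit is the distinct case (one spontaneous report).  Only
drug rows with involvement ``suspected`` contribute.  A case contributes
at most 1 to any (drug, PT) cell, at most 1 to any (drug, category) cell,
and at most 1 per drug to the per-drug irAE / all-reaction counts —
deduplication happens at each aggregation level.  Because combination
regimens list several suspected drugs on one case, a case may count once
for *each* of its suspected drugs: summed over drugs, per-category shares
can exceed 100%.

Three ratio tables are derived:

* drug level — irAE cases / all-reaction cases per drug, in percent;
* PT level — cases with any roster drug suspected / all-drug cases, per PT;
* category level — each drug's share of the all-drug case total of the
  category, the drugs x categories matrix fed to the SOM and the tree.

Displayed percentages are rounded half-up to one decimal; full precision
is retained internally.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._util import canonical_name, round_half_up
from .catalog import IraeCatalog
from .jader_io import ReportCase

__all__ = ["CountTables", "RatioMatrix", "count_cases", "drug_level_ratios",
           "pt_level_ratios", "category_ratio_matrix"]


@dataclass
class CountTables:
    """Distinct-case counts at every aggregation level.

    ``*_total`` maps count cases over *all* suspected drugs, roster or not;
    drug-keyed maps cover roster drugs only.  ``n_pt_roster`` /
    ``n_cat_roster`` count cases with at least one roster drug suspected
    (the union, which is not derivable from per-drug counts when drugs are
    co-suspected on the same case).
    """

    roster: list[str]
    n_drug_pt: Counter = field(default_factory=Counter)
    n_pt_total: Counter = field(default_factory=Counter)
    n_drug_cat: Counter = field(default_factory=Counter)
    n_cat_total: Counter = field(default_factory=Counter)
    n_drug_irae: Counter = field(default_factory=Counter)
    n_drug_all: Counter = field(default_factory=Counter)
    n_pt_roster: Counter = field(default_factory=Counter)
    n_cat_roster: Counter = field(default_factory=Counter)

    def __eq__(self, other: object) -> bool:  # Counters drop zero entries unevenly
        if not isinstance(other, CountTables):
            return NotImplemented
        def clean(c: Counter) -> dict:
            return {k: v for k, v in c.items() if v}
        return self.roster == other.roster and all(
            clean(getattr(self, f)) == clean(getattr(other, f))
            for f in ("n_drug_pt", "n_pt_total", "n_drug_cat", "n_cat_total",
                      "n_drug_irae", "n_drug_all", "n_pt_roster", "n_cat_roster")
        )


@dataclass
class RatioMatrix:
    """Drugs x features matrix of reporting ratios on the 0–100 scale."""

    drugs: list[str]
    features: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drugs), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.drugs)}, {len(self.features)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratio matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drugs, columns=self.features)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RatioMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def row(self, drug: str) -> np.ndarray:
        return self.values[self.drugs.index(drug)]

    def write_csv(self, path: Union[str, Path]) -> None:
        """Machine layout: drugs as rows, features as columns."""
        self.to_frame().rename_axis("drug").to_csv(path)

    def write_paper_layout(self, path: Union[str, Path]) -> None:
        """Publication layout: categories as rows, drugs as columns."""
        self.to_frame().T.rename_axis("category").round(1).to_csv(path)

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "RatioMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls.from_frame(df)


def count_cases(
    cases: Sequence[ReportCase],
    catalog: IraeCatalog,
    drug_roster: Sequence[str],
) -> CountTables:
    """Tally distinct-case counts from joined report cases.

    Only ``suspected`` drug involvement counts.  Reaction PTs are matched
    against the catalog (canonicalized exact match); non-catalog PTs feed
    only the per-drug all-reaction counts.  Drugs outside the roster still
    contribute to the all-drug ``*_total`` maps.
    """
    if not drug_roster:
        raise ValueError("drug_roster must be non-empty")
    roster = list(drug_roster)
    roster_keys = {canonical_name(d): d for d in roster}
    ct = CountTables(roster=roster)

    for case in cases:
        suspected = case.suspected_drugs()
        if not suspected:
            continue
        on_roster = [roster_keys[canonical_name(d)] for d in suspected
                     if canonical_name(d) in roster_keys]
        # case-level deduplicated PT / category sets
        pts: dict[str, None] = {}
        cats: dict[str, None] = {}
        any_reaction = len(case.reactions) > 0
        for r in case.reactions:
            cat = catalog.category_of(r.pt_name)
            if cat is None:
                continue
            pts.setdefault(r.pt_name, None)
            cats.setdefault(cat, None)

        for p in pts:
            ct.n_pt_total[p] += 1
        for c in cats:
            ct.n_cat_total[c] += 1
        if on_roster:
            for p in pts:
                ct.n_pt_roster[p] += 1
            for c in cats:
                ct.n_cat_roster[c] += 1
        for d in on_roster:
            if any_reaction:
                ct.n_drug_all[d] += 1
            if pts:
                ct.n_drug_irae[d] += 1
            for p in pts:
                ct.n_drug_pt[d, p] += 1
            for c in cats:
                ct.n_drug_cat[d, c] += 1
    return ct


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        if num != 0:
            raise ValueError(f"{what}: nonzero numerator with zero denominator")
        warnings.warn(f"zero denominator for {what}; ratio set to 0", stacklevel=3)
        return 0.0
    return 100.0 * num / den


def drug_level_ratios(ct: CountTables) -> pd.DataFrame:
    """Per-drug irAE reporting ratio: irAE cases over all-reaction cases.

    Returns a frame with columns ``drug, case, total, ratio, ratio_display``
    (display rounded half-up to one decimal), one row per roster drug.
    """
    rows = []
    for d in ct.roster:
        case = int(ct.n_drug_irae[d])
        total = int(ct.n_drug_all[d])
        ratio = _safe_ratio(case, total, f"drug {d!r}")
        rows.append((d, case, total, ratio, round_half_up(ratio, 1)))
    return pd.DataFrame(rows, columns=["drug", "case", "total", "ratio", "ratio_display"])


def pt_level_ratios(ct: CountTables, ici_set: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-PT share of the roster drugs in the all-drug case total.

    ``case`` counts cases with *any* roster drug suspected (union, not the
    per-drug sum); ``total`` counts cases under any suspected drug.
    ``ici_set`` must equal the roster the counts were built with — the
    union over an arbitrary subset is not recoverable from counts, so a
    different subset requires re-counting with that subset as roster.
    """
    if ici_set is not None and set(ici_set) != set(ct.roster):
        raise ValueError(
            "ici_set must match the counting roster; re-run count_cases with "
            "the subset as drug_roster to change it"
        )
    rows = []
    for p in sorted(ct.n_pt_total):
        case = int(ct.n_pt_roster[p])
        total = int(ct.n_pt_total[p])
        ratio = _safe_ratio(case, total, f"PT {p!r}")
        rows.append((p, case, total, ratio, round_half_up(ratio, 1)))
    return pd.DataFrame(rows, columns=["pt_name", "case", "total", "ratio", "ratio_display"])


def category_ratio_matrix(
    ct: CountTables,
    drugs: Optional[Sequence[str]] = None,
    catalog: Optional[IraeCatalog] = None,
) -> RatioMatrix:
    """Drug x category matrix: each drug's percent share of the category total.

    The denominator is the all-drug case total of the category, so rows of
    a category may sum above 100% when drugs are co-suspected.  Feature
    order follows ``catalog.categories`` when a catalog is given, else the
    sorted categories present in the counts.  Zero-total categories yield
    a zero column with a warning.
    """
    drugs = list(drugs) if drugs is not None else list(ct.roster)
    if catalog is not None:
        features = list(catalog.categories)
    else:
        features = sorted(set(ct.n_cat_total) | {c for _, c in ct.n_drug_cat})
    vals = np.zeros((len(drugs), len(features)))
    for j, c in enumerate(features):
        den = ct.n_cat_total[c]
        if den == 0:
            warnings.warn(f"zero all-drug total for category {c!r}; column set to 0",
                          stacklevel=2)
            continue
        for i, d in enumerate(drugs):
            vals[i, j] = 100.0 * ct.n_drug_cat[d, c] / den
    return RatioMatrix(drugs, features, vals)


def pt_ratio_matrix(
    ct: CountTables,
    drugs: Optional[Sequence[str]] = None,
    catalog: Optional[IraeCatalog] = None,
) -> RatioMatrix:
    """Same share semantics as :func:`category_ratio_matrix` at PT level.

    Used as the 125-feature input of the large-map SOM.
    """
    drugs = list(drugs) if drugs is not None else list(ct.roster)
    if catalog is not None:
        features = list(catalog.pt_names)
    else:
        features = sorted(set(ct.n_pt_total) | {p for _, p in ct.n_drug_pt})
    vals = np.zeros((len(drugs), len(features)))
    for j, p in enumerate(features):
        den = ct.n_pt_total[p]
        if den == 0:
            continue
        for i, d in enumerate(drugs):
            vals[i, j] = 100.0 * ct.n_drug_pt[d, p] / den
    return RatioMatrix(drugs, features, vals)


def write_ratio_tables(
    ct: CountTables,
    outdir: Union[str, Path],
    catalog: Optional[IraeCatalog] = None,
) -> dict[str, Path]:
    """Write the three ratio tables plus the machine-layout matrix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    df = pt_level_ratios(ct)
    paths["table1"] = outdir / "table1_pt_ratios.csv"
    df.to_csv(paths["table1"], index=False)
    df = drug_level_ratios(ct)
    paths["table2"] = outdir / "table2_drug_ratios.csv"
    df.to_csv(paths["table2"], index=False)
    rm = category_ratio_matrix(ct, catalog=catalog)
    paths["table3"] = outdir / "table3_matrix.csv"
    rm.write_paper_layout(paths["table3"])
    paths["rr_matrix"] = outdir / "rr_matrix.csv"
    rm.write_csv(paths["rr_matrix"])
    return paths
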
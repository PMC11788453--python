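"""Loaders for the packaged reference tables.

The original JADER extract behind the published analysis is a database
snapshot (April 2004 – February 2024) that cannot be redistributed or
re-downloaded reproducibly, so the published summary tables ship with the
package as the canonical bridge between the source analysis and this code:

* per-PT case/total counts and ratios over the eight checkpoint
  inhibitors (125 rows);
* per-drug case/total counts, ratios, and the published 6x1 SOM unit
  assignment (8 rows);
* the 8 x 21 drug-by-category reporting-ratio matrix.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .tables import RatioMatrix

__all__ = ["ICI_DRUGS", "load_pt_counts", "load_drug_counts",
           "load_category_matrix", "load_unit_labels"]

#: The eight immune checkpoint inhibitors, in the published column order.
ICI_DRUGS = [
    "Atezolizumab", "Avelumab", "Cemiplimab", "Durvalumab",
    "Ipilimumab", "Nivolumab", "Pembrolizumab", "Tremelimumab",
]


def _data(name: str) -> Path:
    return Path(str(resources.files("irae_som").joinpath("data", name)))


def load_pt_counts() -> pd.DataFrame:
    """Per-PT ``case`` (eight-inhibitor) and ``total`` (all-drug) counts."""
    return pd.read_csv(_data("pt_report_counts.csv"))


def load_drug_counts() -> pd.DataFrame:
    """Per-drug irAE ``case`` / all-reaction ``total`` counts, ratio, unit."""
    return pd.read_csv(_data("drug_report_counts.csv"))


def load_category_matrix() -> RatioMatrix:
    """The published drug x category reporting-ratio matrix (8 x 21).

    Stored category-major as published; returned drugs-as-rows, with
    categories in the published row order (the feature order that all
    tie-breaks reference).
    """
    df = pd.read_csv(_data("category_ratio_matrix.csv"), index_col=0)
    return RatioMatrix.from_frame(df.T)


def load_unit_labels() -> dict[str, int]:
    """Published 6x1 SOM unit number per drug (the tree's class labels)."""
    df = load_drug_counts()
    return dict(zip(df["drug"], df["unit"].astype(int)))
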
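"""Preferred-term catalog: the MedDRA PT -> irAE-category mapping.

The packaged catalog holds the 125 preferred terms grouped into 21
immune-related adverse-event (irAE) categories that drive every counting
and clustering stage downstream.  Categories are kept in a fixed order
(the order of the packaged category ratio matrix) because that order is
the feature order of the SOM input and the decision-tree predictors, and
tie-breaks depend on it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from ._util import canonical_name

__all__ = ["PtEntry", "IraeCatalog", "CatalogError", "load_catalog", "write_catalog"]


class CatalogError(ValueError):
    """Raised when a catalog file fails validation."""


@dataclass(frozen=True)
class PtEntry:
    """One preferred term with its optional 8-digit MedDRA code and category."""

    pt_name: str
    pt_code: Optional[str]
    category: str


@dataclass
class IraeCatalog:
    """Validated PT -> category mapping with a closed, ordered category set."""

    entries: list[PtEntry]
    categories: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.categories:
            seen: dict[str, None] = {}
            for e in self.entries:
                seen.setdefault(e.category, None)
            self.categories = list(seen)
        self._validate()
        self._lookup = {canonical_name(e.pt_name): e.category for e in self.entries}

    def _validate(self) -> None:
        if not self.entries:
            raise CatalogError("catalog has no entries")
        names: set[str] = set()
        catset = set(self.categories)
        for i, e in enumerate(self.entries):
            if not e.pt_name.strip():
                raise CatalogError(f"entry {i}: empty pt_name")
            key = canonical_name(e.pt_name)
            if key in names:
                raise CatalogError(f"entry {i}: duplicate pt_name {e.pt_name!r}")
            names.add(key)
            if e.category not in catset:
                raise CatalogError(
                    f"entry {i}: category {e.category!r} not in the catalog category set"
                )
        members = {e.category for e in self.entries}
        empty = [c for c in self.categories if c not in members]
        if empty:
            raise CatalogError(f"categories with no member PT: {empty}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def pt_names(self) -> list[str]:
        return [e.pt_name for e in self.entries]

    def category_of(self, pt_name: str) -> Optional[str]:
        """Category of ``pt_name``, or ``None`` for PTs outside the catalog.

        Non-irAE preferred terms are expected in real report data, so a
        missing term is a value, not an error.  Matching is exact after
        canonicalization (case, whitespace, apostrophe/dash variants).
        """
        return self._lookup.get(canonical_name(pt_name))

    def __contains__(self, pt_name: str) -> bool:
        return canonical_name(pt_name) in self._lookup

    def members(self, category: str) -> list[str]:
        return [e.pt_name for e in self.entries if e.category == category]


def category_of(catalog: IraeCatalog, pt_name: str) -> Optional[str]:
    """Functional alias for :meth:`IraeCatalog.category_of`."""
    return catalog.category_of(pt_name)


def _packaged_path(name: str) -> Path:
    return Path(str(resources.files("irae_som").joinpath("data", name)))


def load_catalog(path: Union[str, Path] = "packaged") -> IraeCatalog:
    """Load and validate a PT catalog from CSV (``pt_name,pt_code,category``).

    ``"packaged"`` loads the built-in 125-term / 21-category catalog.
    Duplicate PT names, blank names, or rows that do not parse raise
    :class:`CatalogError` naming the offending row.
    """
    p = _packaged_path("irae_catalog.csv") if path == "packaged" else Path(path)
    entries: list[PtEntry] = []
    with open(p, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"pt_name", "pt_code", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CatalogError(
                f"{p}: header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            name = (row["pt_name"] or "").strip()
            if not name:
                raise CatalogError(f"{p}:{lineno}: empty pt_name")
            code = (row["pt_code"] or "").strip() or None
            cat = (row["category"] or "").strip()
            if not cat:
                raise CatalogError(f"{p}:{lineno}: empty category for {name!r}")
            entries.append(PtEntry(name, code, cat))
    try:
        return IraeCatalog(entries)
    except CatalogError as err:
        raise CatalogError(f"{p}: {err}") from None


def write_catalog(catalog: IraeCatalog, path: Union[str, Path]) -> None:
    """Write a catalog back to the CSV interchange format (round-trippable)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pt_name", "pt_code", "category"])
        for e in catalog.entries:
            writer.writerow([e.pt_name, e.pt_code or "", e.category])


def catalog_from_pairs(pairs: Iterable[tuple[str, str]]) -> IraeCatalog:
    """Build a catalog from (pt_name, category) pairs; convenience for tests."""
    return IraeCatalog([PtEntry(n, None, c) for n, c in pairs])
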
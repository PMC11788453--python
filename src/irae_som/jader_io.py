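"""Read JADER-style four-table spontaneous-report data and join it per case.

The Japanese Adverse Drug Event Report database (JADER) distributes one
row-oriented table per aspect of a report: DEMO (patient), DRUG (one row
per drug per case, with an involvement code), REAC (one row per reported
reaction, as a MedDRA preferred term), and optionally HIST (underlying
disease; parsed but unused by this pipeline).  This module reads delimited
text in that shape and regroups it into case-centric records.

The canonical headers are English (``case_id,sex,age_band,weight_band`` /
``case_id,drug_name,involvement`` / ``case_id,pt_name,onset_date``);
a per-table column map translates alternative headers (e.g. the Japanese
originals) and an encoding argument handles Shift-JIS exports.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

__all__ = [
    "Involvement",
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "ReportCase",
    "JaderTables",
    "TableFormatError",
    "read_tables",
    "join_cases",
    "write_tables",
]

PathLike = Union[str, Path]


class TableFormatError(ValueError):
    """A table file violates the documented schema."""


class Involvement(str, Enum):
    """Drug involvement code attached to each DRUG row."""

    SUSPECTED = "suspected"
    CONCOMITANT = "concomitant"
    INTERACTION = "interaction"


# Accepted spellings for each involvement code (compared case-insensitively).
_INVOLVEMENT_ALIASES: dict[str, Involvement] = {
    "suspected": Involvement.SUSPECTED,
    "suspected drug": Involvement.SUSPECTED,
    "concomitant": Involvement.CONCOMITANT,
    "concomitant drug": Involvement.CONCOMITANT,
    "interaction": Involvement.INTERACTION,
}


@dataclass(frozen=True)
class DemoRecord:
    case_id: str
    sex: Optional[str] = None
    age_band: Optional[str] = None
    weight_band: Optional[str] = None


@dataclass(frozen=True)
class DrugRecord:
    case_id: str
    drug_name: str
    involvement: Involvement


@dataclass(frozen=True)
class ReacRecord:
    case_id: str
    pt_name: str
    onset_date: Optional[str] = None


@dataclass
class ReportCase:
    """One spontaneous report: demographics plus its drug and reaction rows."""

    case_id: str
    demo: Optional[DemoRecord] = None
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReacRecord] = field(default_factory=list)

    def suspected_drugs(self) -> list[str]:
        """Distinct suspected drug names, input order preserved."""
        out: dict[str, None] = {}
        for d in self.drugs:
            if d.involvement is Involvement.SUSPECTED:
                out.setdefault(d.drug_name, None)
        return list(out)


@dataclass
class JaderTables:
    demo: list[DemoRecord]
    drug: list[DrugRecord]
    reac: list[ReacRecord]
    hist: list[dict] = field(default_factory=list)


_CANON_HEADERS = {
    "demo": ["case_id", "sex", "age_band", "weight_band"],
    "drug": ["case_id", "drug_name", "involvement"],
    "reac": ["case_id", "pt_name", "onset_date"],
}


def _read_rows(
    path: PathLike,
    table: str,
    encoding: str,
    column_map: Optional[Mapping[str, str]],
) -> Iterable[tuple[int, dict[str, str]]]:
    want = _CANON_HEADERS[table]
    with open(path, newline="", encoding=encoding) as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        rename = dict(column_map or {})
        canon = [rename.get(h, h) for h in header]
        missing = [c for c in want if c not in canon and c not in ("onset_date",)]
        # sex/age/weight are optional columns of DEMO; only case_id is required there
        if table == "demo":
            missing = [c for c in missing if c == "case_id"]
        if missing:
            raise TableFormatError(
                f"{path}: missing column(s) {missing}; header was {header}"
            )
        for lineno, raw in enumerate(reader, start=2):
            row = {rename.get(k, k): (v or "").strip() for k, v in raw.items() if k}
            if not row.get("case_id"):
                raise TableFormatError(f"{path}:{lineno}: empty case_id")
            yield lineno, row


def read_tables(
    demo_path: PathLike,
    drug_path: PathLike,
    reac_path: PathLike,
    hist_path: Optional[PathLike] = None,
    *,
    encoding: str = "utf-8",
    column_maps: Optional[Mapping[str, Mapping[str, str]]] = None,
    drug_aliases: Optional[Mapping[str, str]] = None,
) -> JaderTables:
    """Parse the DEMO/DRUG/REAC (and optional HIST) tables into typed records.

    ``column_maps`` maps table name ("demo"/"drug"/"reac") to a
    {file-header -> canonical-header} dict; ``drug_aliases`` maps raw drug
    names (brand or Japanese generic) to canonical names at read time.
    Unknown involvement codes and malformed rows raise
    :class:`TableFormatError` with file and line number.
    """
    maps = column_maps or {}
    aliases = {k.strip().lower(): v for k, v in (drug_aliases or {}).items()}

    demo: list[DemoRecord] = []
    seen_demo: set[str] = set()
    for lineno, row in _read_rows(demo_path, "demo", encoding, maps.get("demo")):
        cid = row["case_id"]
        if cid in seen_demo:
            raise TableFormatError(f"{demo_path}:{lineno}: duplicate DEMO case_id {cid!r}")
        seen_demo.add(cid)
        demo.append(
            DemoRecord(cid, row.get("sex") or None, row.get("age_band") or None,
                       row.get("weight_band") or None)
        )

    drug: list[DrugRecord] = []
    for lineno, row in _read_rows(drug_path, "drug", encoding, maps.get("drug")):
        name = row.get("drug_name", "")
        if not name:
            raise TableFormatError(f"{drug_path}:{lineno}: empty drug_name")
        name = aliases.get(name.lower(), name)
        code = row.get("involvement", "").lower()
        inv = _INVOLVEMENT_ALIASES.get(code)
        if inv is None:
            raise TableFormatError(
                f"{drug_path}:{lineno}: unknown involvement code {row.get('involvement')!r}"
            )
        drug.append(DrugRecord(row["case_id"], name, inv))

    reac: list[ReacRecord] = []
    for lineno, row in _read_rows(reac_path, "reac", encoding, maps.get("reac")):
        pt = row.get("pt_name", "")
        if not pt:
            raise TableFormatError(f"{reac_path}:{lineno}: empty pt_name")
        reac.append(ReacRecord(row["case_id"], pt, row.get("onset_date") or None))

    hist: list[dict] = []
    if hist_path is not None:
        with open(hist_path, newline="", encoding=encoding) as fh:
            hist = [dict(r) for r in csv.DictReader(fh)]

    return JaderTables(demo, drug, reac, hist)


def join_cases(tables: JaderTables) -> list[ReportCase]:
    """Group the parsed tables into one :class:`ReportCase` per case_id.

    Every case_id appearing in any table yields a case; cases lacking a
    DEMO row keep ``demo=None`` and orphan reaction- or drug-only cases are
    retained.  Output order is first-appearance order across DEMO, DRUG,
    REAC, and no child record is dropped or duplicated.
    """
    cases: dict[str, ReportCase] = {}

    def case(cid: str) -> ReportCase:
        if cid not in cases:
            cases[cid] = ReportCase(cid)
        return cases[cid]

    for d in tables.demo:
        case(d.case_id).demo = d
    for r in tables.drug:
        case(r.case_id).drugs.append(r)
    for r in tables.reac:
        case(r.case_id).reactions.append(r)
    return list(cases.values())


def write_tables(tables: JaderTables, outdir: PathLike) -> dict[str, Path]:
    """Write tables back to canonical CSV files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "demo": outdir / "demo.csv",
        "drug": outdir / "drug.csv",
        "reac": outdir / "reac.csv",
    }
    with open(paths["demo"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CANON_HEADERS["demo"])
        for d in tables.demo:
            w.writerow([d.case_id, d.sex or "", d.age_band or "", d.weight_band or ""])
    with open(paths["drug"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CANON_HEADERS["drug"])
        for r in tables.drug:
            w.writerow([r.case_id, r.drug_name, r.involvement.value])
    with open(paths["reac"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CANON_HEADERS["reac"])
        for r in tables.reac:
            w.writerow([r.case_id, r.pt_name, r.onset_date or ""])
    return paths
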
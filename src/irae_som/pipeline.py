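"""End-to-end runs: simulate/read -> count -> ratios -> SOM -> tree -> rules.

A run is configured once (input mode, catalog, roster, SOM and tree
settings, seed), executes the staged pipeline, and leaves every
intermediate artifact plus a ``manifest.json`` (config echo, stage
timings, machine-parseable warnings) in the output directory, so every
number in the final summary is traceable to a file.

Input modes:

* ``synthetic`` — generate tables from a preset or explicit generator
  config, then run the full pipeline on the written files;
* ``tables`` — read existing DEMO/DRUG/REAC csv files;
* ``matrix-fixture`` — start from the packaged published ratio matrix
  and unit labels and run only the SOM and/or the tree.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import fixtures, jader_io, synthetic, tables
from .cart import CartConfig, extract_rules, grow
from .catalog import load_catalog
from .som import SomConfig, partition_of, train, unit_distance_summary

__all__ = ["RunConfig", "run", "report"]


@dataclass
class RunConfig:
    mode: str = "matrix-fixture"  # "synthetic" | "tables" | "matrix-fixture"
    outdir: Union[str, Path] = "run"
    seed: int = 0
    # synthetic mode
    preset: str = "table3like"
    # tables mode
    demo_path: Optional[str] = None
    drug_path: Optional[str] = None
    reac_path: Optional[str] = None
    # analysis settings
    catalog_path: str = "packaged"
    roster: Optional[Sequence[str]] = None
    som: SomConfig = field(default_factory=SomConfig)
    cart: CartConfig = field(default_factory=CartConfig)
    stages: Sequence[str] = ("som", "tree")  # matrix-fixture sub-selection

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "tables", "matrix-fixture"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "tables" and not (self.demo_path and self.drug_path and self.reac_path):
            raise ValueError("tables mode needs demo_path, drug_path and reac_path")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def run(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns the manifest dict.

    Any stage error aborts the run with the stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _jsonable(config),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "artifacts": {},
    }
    caught: list[str] = []

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.ctx = warnings.catch_warnings(record=True)
                self_inner.log = self_inner.ctx.__enter__()
                warnings.simplefilter("always")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                self_inner.ctx.__exit__(None, None, None)
                if exc_type is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                for w in self_inner.log:
                    caught.append(f"{name}: {w.message}")
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 4)
                }
                return False

        return _Stage()

    catalog = load_catalog(config.catalog_path)
    som_cfg = dataclasses.replace(config.som, seed=config.seed)

    if config.mode == "matrix-fixture":
        matrix = fixtures.load_category_matrix()
        labels_map = fixtures.load_unit_labels()
    else:
        if config.mode == "synthetic":
            with stage("simulate"):
                sim_cfg = synthetic.preset_profiles(config.preset, catalog)
                sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
                tbls, gt = synthetic.simulate(sim_cfg, catalog)
                paths = jader_io.write_tables(tbls, outdir / "tables")
                synthetic.ground_truth_to_json(gt, outdir / "tables" / "ground_truth.json")
                manifest["artifacts"].update(
                    {f"tables.{k}": str(v) for k, v in paths.items()})
                manifest["artifacts"]["tables.ground_truth"] = str(
                    outdir / "tables" / "ground_truth.json")
                demo_p, drug_p, reac_p = paths["demo"], paths["drug"], paths["reac"]
        else:
            demo_p, drug_p, reac_p = config.demo_path, config.drug_path, config.reac_path

        with stage("count"):
            tbls = jader_io.read_tables(demo_p, drug_p, reac_p)
            cases = jader_io.join_cases(tbls)
            roster = list(config.roster) if config.roster else sorted(
                {r.drug_name for r in tbls.drug})
            ct = tables.count_cases(cases, catalog, roster)
        with stage("ratios"):
            paths = tables.write_ratio_tables(ct, outdir, catalog)
            manifest["artifacts"].update({k: str(v) for k, v in paths.items()})
            matrix = tables.category_ratio_matrix(ct, catalog=catalog)
        labels_map = None

    model = None
    if config.mode != "matrix-fixture" or "som" in config.stages:
        with stage("som"):
            model = train(som_cfg, matrix)
            units = [(d, *model.unit_coords(u), u) for d, u in model.assignments.items()]
            import pandas as pd

            pd.DataFrame(units, columns=["drug", "unit_row", "unit_col", "unit_index"]).to_csv(
                outdir / "som_units.csv", index=False)
            pd.DataFrame(model.weights,
                         columns=model.feature_names).to_csv(outdir / "som_weights.csv",
                                                             index_label="unit")
            unit_distance_summary(model).to_csv(outdir / "som_udist.csv", index=False)
            manifest["artifacts"]["som_units"] = str(outdir / "som_units.csv")
            manifest["artifacts"]["som_weights"] = str(outdir / "som_weights.csv")
            manifest["artifacts"]["som_udist"] = str(outdir / "som_udist.csv")
            manifest["som"] = {
                "assignments": model.assignments,
                "quantization_error": model.quantization_error,
                "partition": sorted(sorted(g) for g in partition_of(model)),
            }

    if config.mode != "matrix-fixture" or "tree" in config.stages:
        with stage("tree"):
            if labels_map is not None:
                labels = [labels_map[d] for d in matrix.drugs]
            else:
                labels = [model.assignments[d] for d in matrix.drugs]
            tree = grow(matrix, labels, config.cart)
            tree.to_json(outdir / "tree.json")
            rules = extract_rules(tree)
            (outdir / "rules.txt").write_text("\n".join(rules) + "\n", encoding="utf-8")
            manifest["artifacts"]["tree"] = str(outdir / "tree.json")
            manifest["artifacts"]["rules"] = str(outdir / "rules.txt")
            manifest["tree"] = {
                "n_leaves": len(tree.leaves()),
                "splits": [
                    {"feature": nd.split_feature, "threshold": nd.threshold}
                    for nd in tree.internal_nodes()
                ],
            }

    manifest["warnings"] = caught
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def report(run_dir: Union[str, Path]) -> str:
    """Human-readable markdown summary of a completed run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing {manifest_path}: not a completed run directory")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    lines = ["# Run summary", "", f"seed: {manifest['seed']}", ""]

    table2 = run_dir / "table2_drug_ratios.csv"
    if table2.exists():
        import pandas as pd

        df = pd.read_csv(table2)
        lines += ["## Drug-level reporting ratios", "", df.to_string(index=False), ""]
    if "som" in manifest:
        lines += ["## SOM unit assignments", ""]
        for d, u in sorted(manifest["som"]["assignments"].items()):
            lines.append(f"- {d}: unit {u}")
        lines += ["", f"quantization error: {manifest['som']['quantization_error']:.4f}", ""]
    rules_path = run_dir / "rules.txt"
    if rules_path.exists():
        lines += ["## Decision rules", ""]
        lines += rules_path.read_text(encoding="utf-8").strip().splitlines()
        lines.append("")
    if manifest.get("warnings"):
        lines += ["## Warnings", ""] + [f"- {w}" for w in manifest["warnings"]] + [""]
    return "\n".join(lines)
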
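"""Kohonen self-organizing map by online competitive learning.

A rectangular grid of units, each carrying a weight vector of the input
dimension, is trained by presenting input rows one at a time: the unit
whose weights are nearest the input (best-matching unit, BMU) and its
grid neighbors move toward the input.  Learning rate and neighborhood
radius both decay linearly to zero over the run, so the map orders itself
coarsely early on and fine-tunes locally at the end.  Inputs here are
drug profile vectors (rows of a reporting-ratio matrix); drugs assigned
to the same unit after training share an adverse-event profile group.

Defaults emulate the classic R SOM package the analysis was built on:
bubble neighborhood on Chebyshev grid distance, sample initialization,
alpha0 = 0.05, radius0 = ceil(max(grid dims)/2), n_iter = 100 x n_rows.
Features are left unscaled by default — category reporting ratios are
already commensurate percentages — with optional z-scaling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .tables import RatioMatrix

__all__ = ["SomConfig", "SomModel", "init_weights", "find_bmu", "train",
           "partition_of", "unit_distance_summary"]

_GAUSS_RADIUS_FLOOR = 1e-2  # keeps the Gaussian kernel finite as r(t) -> 0


@dataclass(frozen=True)
class SomConfig:
    grid_rows: int = 6
    grid_cols: int = 1
    n_iter: Optional[int] = None  # None -> 100 x n_rows
    alpha0: float = 0.05
    radius0: Optional[float] = None  # None -> ceil(max(grid dims)/2)
    neighborhood: str = "bubble"  # "bubble" | "gaussian"
    init: str = "sample"  # "sample" | "uniform-random"
    scale_features: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1 or self.grid_rows * self.grid_cols < 2:
            raise ValueError("grid must have at least 2 units")
        if not (0.0 < self.alpha0 <= 1.0):
            raise ValueError("alpha0 must be in (0, 1]")
        if self.radius0 is not None and self.radius0 < 0:
            raise ValueError("radius0 must be >= 0")
        if self.neighborhood not in ("bubble", "gaussian"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.init not in ("sample", "uniform-random"):
            raise ValueError(f"unknown init {self.init!r}")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def resolved_radius0(self) -> float:
        if self.radius0 is not None:
            return float(self.radius0)
        return float(int(np.ceil(max(self.grid_rows, self.grid_cols) / 2)))

    def resolved_n_iter(self, n_rows: int) -> int:
        return self.n_iter if self.n_iter is not None else 100 * n_rows


@dataclass
class SomModel:
    config: SomConfig
    weights: np.ndarray  # (n_units, n_features), row-major grid order
    assignments: dict[str, int]  # drug -> unit index
    quantization_error: float
    feature_names: list[str] = field(default_factory=list)
    scale_mean: Optional[np.ndarray] = None
    scale_std: Optional[np.ndarray] = None

    def unit_coords(self, unit: int) -> tuple[int, int]:
        return divmod(unit, self.config.grid_cols)


def _grid_coords(config: SomConfig) -> np.ndarray:
    rows, cols = np.divmod(np.arange(config.n_units), config.grid_cols)
    return np.stack([rows, cols], axis=1)


def _scaled(data: RatioMatrix, config: SomConfig):
    X = np.asarray(data.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite values")
    if not config.scale_features:
        return X, None, None
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    return (X - mean) / std, mean, std


def init_weights(config: SomConfig, data: RatioMatrix,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Seed-deterministic initial weights.

    ``sample`` draws data rows with replacement; ``uniform-random`` draws
    each feature uniformly within its observed [min, max] range.
    """
    if len(data.drugs) == 0:
        raise ValueError("cannot initialize from empty data")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    X, _, _ = _scaled(data, config)
    if config.init == "sample":
        idx = rng.integers(0, X.shape[0], size=config.n_units)
        return X[idx].copy()
    lo, hi = X.min(axis=0), X.max(axis=0)
    return rng.uniform(lo, hi, size=(config.n_units, X.shape[1]))


def find_bmu(weights: np.ndarray, x: np.ndarray) -> int:
    """Index of the unit with minimal Euclidean distance to ``x``.

    Ties break to the lowest unit index (row-major grid order).
    """
    weights = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    if weights.ndim != 2 or x.shape != (weights.shape[1],):
        raise ValueError(f"dimension mismatch: weights {weights.shape}, x {x.shape}")
    d2 = np.sum((weights - x) ** 2, axis=1)
    return int(np.argmin(d2))  # argmin returns the first minimum -> lowest index


def train(config: SomConfig, data: RatioMatrix) -> SomModel:
    """Online competitive learning over ``n_iter`` presentations.

    Inputs are cycled in a seeded random order reshuffled each epoch.  At
    step t, alpha(t) = alpha0 (1 - t/n_iter) and r(t) = radius0 (1 - t/n_iter);
    the bubble kernel updates every unit within Chebyshev grid distance
    r(t) of the BMU with weight 1, the Gaussian kernel uses
    exp(-d^2 / 2 r(t)^2) with the radius floored at a small constant.
    """
    n_rows = len(data.drugs)
    if n_rows == 0:
        raise ValueError("no data rows")
    rng = np.random.default_rng(config.seed)
    X, mean, std = _scaled(data, config)
    weights = init_weights(config, data, rng=rng)
    n_iter = config.resolved_n_iter(n_rows)
    radius0 = config.resolved_radius0()
    coords = _grid_coords(config)

    order = np.empty(0, dtype=int)
    pos = 0
    for t in range(n_iter):
        if pos >= len(order):
            order = rng.permutation(n_rows)
            pos = 0
        x = X[order[pos]]
        pos += 1
        frac = 1.0 - t / n_iter
        alpha = config.alpha0 * frac
        r = radius0 * frac
        bmu = find_bmu(weights, x)
        gdist = np.max(np.abs(coords - coords[bmu]), axis=1)  # Chebyshev
        if config.neighborhood == "bubble":
            h = (gdist <= r).astype(float)
        else:
            rr = max(r, _GAUSS_RADIUS_FLOOR)
            h = np.exp(-(gdist.astype(float) ** 2) / (2.0 * rr * rr))
        weights += alpha * h[:, None] * (x - weights)

    assignments = {d: find_bmu(weights, X[i]) for i, d in enumerate(data.drugs)}
    qe = float(np.mean([np.linalg.norm(X[i] - weights[assignments[d]])
                        for i, d in enumerate(data.drugs)]))
    return SomModel(config=config, weights=weights, assignments=assignments,
                    quantization_error=qe, feature_names=list(data.features),
                    scale_mean=mean, scale_std=std)


def partition_of(model_or_assignments) -> frozenset[frozenset[str]]:
    """Label-invariant partition: the set of unit-sharing drug groups.

    Accepts a trained :class:`SomModel` or a plain {drug -> label} map, so
    published unit columns compare directly against trained maps.
    """
    if isinstance(model_or_assignments, SomModel):
        assignments = model_or_assignments.assignments
    else:
        assignments = dict(model_or_assignments)
    groups: dict[int, set[str]] = {}
    for drug, unit in assignments.items():
        groups.setdefault(unit, set()).add(drug)
    return frozenset(frozenset(g) for g in groups.values())


def unit_distance_summary(model: SomModel):
    """Euclidean weight distance for every grid-adjacent unit pair.

    A text surrogate for the U-matrix view of the trained map: adjacent
    units with small distances hold similar profiles.  Adjacency is
    4-neighborhood on the rectangular grid.
    """
    import pandas as pd

    cfg = model.config
    rows = []
    for u in range(cfg.n_units):
        r, c = divmod(u, cfg.grid_cols)
        for dr, dc in ((0, 1), (1, 0)):
            r2, c2 = r + dr, c + dc
            if r2 < cfg.grid_rows and c2 < cfg.grid_cols:
                v = r2 * cfg.grid_cols + c2
                dist = float(np.linalg.norm(model.weights[u] - model.weights[v]))
                rows.append((u, v, dist))
    return pd.DataFrame(rows, columns=["unit_a", "unit_b", "distance"])


def modal_partition(config: SomConfig, data: RatioMatrix, n_seeds: int,
                    base_seed: int = 0) -> tuple[frozenset[frozenset[str]], float]:
    """Most frequent partition over ``n_seeds`` training runs.

    Returns the modal partition and its frequency in [0, 1].  Used both to
    stabilize the stochastic clustering and as a negative control: on
    exchangeable (structure-free) data no partition dominates.
    """
    from collections import Counter

    counts: Counter = Counter()
    for k in range(n_seeds):
        cfg = dataclasses.replace(config, seed=base_seed + k)
        counts[partition_of(train(cfg, data))] += 1
    part, n = counts.most_common(1)[0]
    return part, n / n_seeds
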
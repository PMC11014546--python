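"""Synthetic perturbation/control profiles and the method benchmark.

The generator emulates the simplest signal-in-noise screen: control features
are i.i.d. draws from the null family (standard normal by default) and a
perturbation shifts the location of a chosen fraction of features by
``shift`` (default 1 standard deviation, i.e. perturbed features ~ N(1, 1)).
The benchmark sweeps a grid of (feature count, perturbed fraction,
replicates, controls) conditions and reports, per method, the recall: the
fraction of simulated perturbations called significant at raw p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import baselines
from .ranking import BinaryRankList, DistanceSpec, average_precision, mean_average_precision
from .ranking import relevance_from_distances
from .significance import DEFAULT_MAX_EXACT, bh_fdr, map_p_value

logger = logging.getLogger(__name__)

NULL_FAMILIES = ("normal", "cauchy")

#: the benchmark grid dimensions reported in the study conditions
GRID_N_FEATURES = (100, 200, 500, 1000, 2500, 5000)
GRID_FRACTIONS = (0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64)
GRID_N_REPLICATES = (2, 3, 4)
GRID_N_CONTROLS = (12, 24, 36)

METHODS = ("map", "mp_value", "mmd", "kmeans")


@dataclass(frozen=True)
class SimulationConfig:
    """One cell of the simulation grid."""

    n_features: int = 100
    frac_perturbed: float = 0.0
    n_replicates: int = 2
    n_controls: int = 12
    n_perturbations: int = 100
    null_family: str = "normal"
    shift: float = 1.0
    scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_perturbed <= 1.0:
            raise ValueError("frac_perturbed must lie in [0, 1]")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if self.null_family not in NULL_FAMILIES:
            raise ValueError(f"unknown null_family {self.null_family!r}")

    @property
    def n_perturbed_features(self) -> int:
        return int(round(self.frac_perturbed * self.n_features))


def _draw(rng: np.random.Generator, family: str, loc: float, scale: float,
          size: tuple[int, ...]) -> np.ndarray:
    if family == "normal":
        return rng.normal(loc, scale, size=size)
    return loc + scale * rng.standard_cauchy(size=size)


def simulate_condition(
    config: SimulationConfig,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n_perturbations`` independent (treatment, control) pairs.

    Treatment replicates have the first ``round(f * d)`` features drawn from
    the shifted family and the rest from the null family; control replicates
    are entirely null. Fresh controls per perturbation; bit-reproducible from
    the seed.
    """
    d = config.n_features
    k = config.n_perturbed_features
    children = np.random.SeedSequence(config.seed).spawn(config.n_perturbations)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        treat = _draw(rng, config.null_family, 0.0, config.scale,
                      (config.n_replicates, d))
        if k:
            treat[:, :k] = _draw(
                rng, config.null_family, config.shift, config.scale,
                (config.n_replicates, k),
            )
        ctrl = _draw(rng, config.null_family, 0.0, config.scale,
                     (config.n_controls, d))
        out.append((treat, ctrl))
    return out


def map_activity_p(
    treatment: np.ndarray,
    control: np.ndarray,
    distance: str | DistanceSpec = "cosine",
    n_perm: int = 10_000,
    seed: int | None = 0,
    max_exact: int = DEFAULT_MAX_EXACT,
) -> tuple[float, float]:
    """(mAP, permutation p-value) for one treatment group against controls."""
    spec = distance if isinstance(distance, DistanceSpec) else DistanceSpec(metric=distance)
    M = len(treatment)
    aps = []
    X = np.vstack([treatment, control])
    D = cdist(treatment, X, metric=spec.scipy_metric)
    for i in range(M):
        cand = np.delete(np.arange(len(X)), i)
        is_pos = cand < M
        rel = relevance_from_distances(D[i][cand], is_pos, tie_order=cand)
        aps.append(average_precision(BinaryRankList(rel, query_id=i)))
    ms = mean_average_precision(aps)
    p = map_p_value(ms, n_perm=n_perm, seed=seed, max_exact=max_exact)
    return ms.value, p


@dataclass(frozen=True)
class BenchmarkRow:
    """Recall of one method on one simulation-grid cell."""

    config: SimulationConfig
    method: str
    recall: float

    def to_dict(self) -> dict:
        return {
            "n_features": self.config.n_features,
            "frac_perturbed": self.config.frac_perturbed,
            "n_replicates": self.config.n_replicates,
            "n_controls": self.config.n_controls,
            "null_family": self.config.null_family,
            "shift": self.config.shift,
            "scale": self.config.scale,
            "n_perturbations": self.config.n_perturbations,
            "seed": self.config.seed,
            "method": self.method,
            "recall": self.recall,
        }


def _method_recall(
    method: str,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    alpha: float,
    n_perm_map: int,
    n_perm_baseline: int,
    seed: int | None,
    corrected: bool,
) -> float:
    p_values: list[float] = []
    detected: list[bool] = []
    for i, (treat, ctrl) in enumerate(pairs):
        child = None if seed is None else (seed + i) % (2**31)
        if method == "map":
            _, p = map_activity_p(treat, ctrl, n_perm=n_perm_map, seed=seed)
            p_values.append(p)
        elif method == "mp_value":
            p_values.append(
                baselines.mp_value(treat, ctrl, n_perm=n_perm_baseline, seed=child).p_value
            )
        elif method == "mmd":
            p_values.append(
                baselines.mmd_test(treat, ctrl, n_perm=n_perm_baseline, seed=child).p_value
            )
        elif method == "kmeans":
            detected.append(baselines.kmeans_separation(treat, ctrl, seed=child).detected)
        else:
            raise ValueError(f"unknown method {method!r}")
    if method == "kmeans":
        return float(np.mean(detected))
    p_arr = np.asarray(p_values)
    if corrected:
        p_arr = bh_fdr(p_arr)
    return float(np.mean(p_arr < alpha))


def run_benchmark(
    grid: Sequence[SimulationConfig],
    methods: Sequence[str] = METHODS,
    seed: int | None = None,
    alpha: float = 0.05,
    n_perm_map: int = 10_000,
    n_perm_baseline: int = baselines.DEFAULT_N_PERM,
    corrected: bool = False,
) -> list[BenchmarkRow]:
    """Recall per (grid cell, method).

    ``seed``, when given, overrides each cell's configured seed through a
    per-cell spawn so the whole benchmark is reproducible from one integer.
    Recall uses raw p-values at ``alpha`` (the study convention); pass
    ``corrected=True`` for a BH-corrected variant. A method failing on a cell
    is logged and its row omitted.
    """
    if not grid or not methods:
        raise ValueError("grid and methods must be nonempty")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    rows: list[BenchmarkRow] = []
    if seed is not None:
        cell_seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(len(grid))
        ]
        grid = [replace(cfg, seed=s) for cfg, s in zip(grid, cell_seeds)]
    for cfg in grid:
        pairs = simulate_condition(cfg)
        for method in methods:
            try:
                recall = _method_recall(
                    method, pairs, alpha, n_perm_map, n_perm_baseline, cfg.seed,
                    corrected,
                )
            except Exception:
                logger.exception(
                    "method %s failed on cell %r; row omitted", method, cfg
                )
                continue
            rows.append(BenchmarkRow(cfg, method, recall))
    return rows


def full_grid(
    n_features: Sequence[int] = GRID_N_FEATURES,
    fractions: Sequence[float] = GRID_FRACTIONS,
    n_replicates: Sequence[int] = GRID_N_REPLICATES,
    n_controls: Sequence[int] = GRID_N_CONTROLS,
    **common,
) -> list[SimulationConfig]:
    """The full benchmark design (6 x 7 x 3 x 3 = 378 cells by default)."""
    return [
        SimulationConfig(
            n_features=d, frac_perturbed=f, n_replicates=m, n_controls=n, **common
        )
        for d in n_features
        for f in fractions
        for m in n_replicates
        for n in n_controls
    ]


def recall_table(rows: Sequence[BenchmarkRow]) -> pd.DataFrame:
    """Tidy long-format table keyed by (cell parameters, method)."""
    if not rows:
        raise ValueError("no benchmark rows")
    df = pd.DataFrame([r.to_dict() for r in rows])
    key = ["n_features", "frac_perturbed", "n_replicates", "n_controls",
           "null_family", "shift", "scale", "method"]
    if df.duplicated(subset=key).any():
        raise ValueError("duplicate (cell, method) keys in benchmark rows")
    return df
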
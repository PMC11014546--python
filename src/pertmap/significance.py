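"""Permutation null distributions for AP/mAP, p-values, and FDR control.

Under the exchangeability null, the binary rank list of a query is a uniform
random arrangement of ``n_pos`` ones among ``n_total`` slots, so the AP null
depends only on (n_pos, n_total) and has exactly C(n_total, n_pos) outcomes.
The distribution is enumerated exactly when that count is small and sampled
by Monte Carlo otherwise. The group-level mAP null is the mean of the
queries' independent null APs; Monte-Carlo p-values use the add-one smoothed
estimator (b+1)/(n+1) so they are valid permutation p-values and never zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .ranking import APScore, MAPScore

#: exact enumeration auto-selected when C(n_total, n_pos) is at most this
DEFAULT_MAX_EXACT = 10_000
DEFAULT_N_PERM = 10_000

_EPS = 1e-12

_NULL_CACHE: dict[tuple, "NullDistribution"] = {}
_MAP_NULL_CACHE: dict[tuple, np.ndarray] = {}


def clear_caches() -> None:
    _NULL_CACHE.clear()
    _MAP_NULL_CACHE.clear()


@dataclass
class NullDistribution:
    """AP distribution under label exchangeability for one (n_pos, n_total).

    ``exact`` mode holds the collapsed support with probabilities; the
    ``monte_carlo`` mode holds sampled AP values.
    """

    n_pos: int
    n_total: int
    mode: str
    values: np.ndarray
    probabilities: np.ndarray | None = None
    n_samples: int | None = None
    seed: int | None = None

    @property
    def mean(self) -> float:
        if self.mode == "exact":
            return float(np.dot(self.values, self.probabilities))
        return float(self.values.mean())

    def tail_probability(self, x: float) -> float:
        """P(AP >= x) under the null (exact mode only)."""
        if self.mode != "exact":
            raise ValueError("exact tail probability requires an exact null")
        return float(self.probabilities[self.values >= x - _EPS].sum())

    def cdf(self, x: np.ndarray) -> np.ndarray:
        """P(AP <= x), used for exact-vs-Monte-Carlo agreement checks."""
        x = np.asarray(x, dtype=float)
        if self.mode == "exact":
            order = np.argsort(self.values)
            v = self.values[order]
            c = np.cumsum(self.probabilities[order])
            idx = np.searchsorted(v, x + _EPS, side="right") - 1
            return np.where(idx >= 0, c[np.clip(idx, 0, None)], 0.0)
        return np.searchsorted(np.sort(self.values), x + _EPS, side="right") / len(
            self.values
        )

    def sample_ap(self, size, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "exact":
            return rng.choice(self.values, size=size, p=self.probabilities)
        idx = rng.integers(0, len(self.values), size=size)
        return self.values[idx]


def _enumerate_ap(n_pos: int, n_total: int) -> np.ndarray:
    """AP of every positive-position configuration (C(n_total, n_pos) values)."""
    combos = np.fromiter(
        itertools.chain.from_iterable(
            itertools.combinations(range(n_total), n_pos)
        ),
        dtype=np.int64,
    ).reshape(-1, n_pos)
    ranks = np.arange(1, n_pos + 1, dtype=float)
    return (ranks / (combos + 1.0)).mean(axis=1)


def _sample_ap_null(
    n_pos: int, n_total: int, n_samples: int, rng: np.random.Generator,
    chunk: int = 20_000,
) -> np.ndarray:
    out = np.empty(n_samples)
    done = 0
    while done < n_samples:
        m = min(chunk, n_samples - done)
        u = rng.random((m, n_total))
        pos = np.argpartition(u, n_pos - 1, axis=1)[:, :n_pos]
        pos.sort(axis=1)
        ranks = np.arange(1, n_pos + 1, dtype=float)
        out[done : done + m] = (ranks / (pos + 1.0)).mean(axis=1)
        done += m
    return out


def null_ap(
    n_pos: int,
    n_total: int,
    mode: str = "auto",
    n_samples: int = 100_000,
    seed: int | None = None,
    max_exact: int = DEFAULT_MAX_EXACT,
) -> NullDistribution:
    """Null AP distribution for given list shape.

    ``mode='auto'`` enumerates exactly when C(n_total, n_pos) <= ``max_exact``
    and falls back to Monte Carlo otherwise. Results are cached: a screen
    reuses the same configuration thousands of times.
    """
    if not (1 <= n_pos < n_total):
        raise ValueError(f"require 1 <= n_pos < n_total, got ({n_pos}, {n_total})")
    if mode not in {"auto", "exact", "monte_carlo"}:
        raise ValueError(f"unknown mode {mode!r}")
    n_config = math.comb(n_total, n_pos)
    if mode == "auto":
        mode = "exact" if n_config <= max_exact else "monte_carlo"
    if mode == "exact" and n_config > max_exact:
        raise ValueError(
            f"exact enumeration requested but C({n_total},{n_pos})={n_config} "
            f"exceeds cap {max_exact}"
        )
    key = (n_pos, n_total, mode, n_samples if mode == "monte_carlo" else None,
           seed if mode == "monte_carlo" else None)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    if mode == "exact":
        aps = _enumerate_ap(n_pos, n_total)
        values, counts = np.unique(aps, return_counts=True)
        null = NullDistribution(
            n_pos, n_total, "exact", values, counts / counts.sum()
        )
    else:
        rng = np.random.default_rng(seed)
        values = _sample_ap_null(n_pos, n_total, n_samples, rng)
        null = NullDistribution(
            n_pos, n_total, "monte_carlo", values, None, n_samples, seed
        )
    _NULL_CACHE[key] = null
    return null


def _null_map_samples(
    configs: tuple[tuple[int, int], ...],
    n_perm: int,
    seed: int | None,
    max_exact: int,
) -> np.ndarray:
    """Sampled null mAP values: mean over queries of independent null APs."""
    key = (configs, n_perm, seed, max_exact)
    if key in _MAP_NULL_CACHE:
        return _MAP_NULL_CACHE[key]
    rng = np.random.default_rng(seed)
    total = np.zeros(n_perm)
    for n_pos, n_total in configs:
        null = null_ap(n_pos, n_total, max_exact=max_exact, seed=seed)
        total += null.sample_ap(n_perm, rng)
    samples = total / len(configs)
    _MAP_NULL_CACHE[key] = samples
    return samples


def map_p_value(
    map_score: MAPScore | float,
    null: NullDistribution | Sequence[NullDistribution] | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    max_exact: int = DEFAULT_MAX_EXACT,
) -> float:
    """Permutation p-value of an observed mAP.

    For a single query with an exact null, the p-value is the exact tail
    probability P(AP >= observed). Otherwise the mAP null is built by drawing
    ``n_perm`` permutations, each averaging one independent null AP per query,
    and the p-value is the smoothed upper-tail fraction.
    """
    if isinstance(map_score, MAPScore):
        observed = map_score.value
        if map_score.ap_scores:
            configs = tuple((s.n_pos, s.n_total) for s in map_score.ap_scores)
        elif null is not None:
            configs = None
        else:
            raise ValueError("MAPScore carries no member APs and no null was given")
    else:
        observed = float(map_score)
        configs = None

    if null is not None:
        nulls = [null] if isinstance(null, NullDistribution) else list(null)
        if configs is not None:
            if len(nulls) == 1:
                nulls = nulls * len(configs)
            if len(nulls) != len(configs):
                raise ValueError("one null per query required")
            for nd, (p, t) in zip(nulls, configs):
                if (nd.n_pos, nd.n_total) != (p, t):
                    raise ValueError(
                        f"null parameters ({nd.n_pos},{nd.n_total}) do not match "
                        f"query list shape ({p},{t})"
                    )
        configs = tuple((nd.n_pos, nd.n_total) for nd in nulls)
        if len(nulls) == 1 and nulls[0].mode == "exact":
            return nulls[0].tail_probability(observed)
    elif configs is None:
        raise ValueError("either a MAPScore with members or a null must be given")
    elif len(configs) == 1:
        nd = null_ap(*configs[0], max_exact=max_exact, seed=seed)
        if nd.mode == "exact":
            return nd.tail_probability(observed)

    samples = _null_map_samples(configs, n_perm, seed, max_exact)
    b = int((samples >= observed - _EPS).sum())
    return (1 + b) / (1 + n_perm)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SignificanceResult:
    """mAP of one query group with raw and FDR-corrected significance."""

    group_id: Any
    map_score: MAPScore
    p_value: float
    corrected_p: float | None = None
    alpha: float = 0.05

    @property
    def map(self) -> float:
        return self.map_score.value

    @property
    def retrieved(self) -> bool | None:
        if self.corrected_p is None:
            return None
        return bool(self.corrected_p < self.alpha)

    @property
    def n_queries(self) -> int:
        return self.map_score.n_queries

    @property
    def n_pos(self) -> int:
        return self.map_score.ap_scores[0].n_pos

    @property
    def n_total(self) -> int:
        return self.map_score.ap_scores[0].n_total


def correct_results(
    results: Sequence[SignificanceResult], alpha: float = 0.05
) -> list[SignificanceResult]:
    """Attach BH q-values (in place) across a batch of group results."""
    results = list(results)
    if not results:
        return results
    q = bh_fdr([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.corrected_p = float(qi)
        r.alpha = alpha
    return results


def percent_retrieved(
    results: Sequence[SignificanceResult], alpha: float = 0.05
) -> float:
    """Percentage of groups with corrected p-value below ``alpha``."""
    results = list(results)
    if not results:
        raise ValueError("empty result list")
    hits = sum(1 for r in results if r.corrected_p is not None and r.corrected_p < alpha)
    return 100.0 * hits / len(results)
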
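"""Tabular profile containers, I/O, normalization and consensus aggregation.

A profile table is a flat table whose rows are profiles (well-level
replicates, consensus profiles, or single cells) and whose columns split into
*metadata* (identifiers: perturbation, plate, well, control flag, ...) and
*features* (a numeric matrix, one dimension per column). By community
convention metadata columns are identified by the ``Metadata_`` name prefix;
an explicit column list overrides the convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

METADATA_PREFIX = "Metadata_"

#: consistency constant making the MAD estimate the standard deviation under
#: normality
MAD_SCALE = 1.4826


class ProfileTableError(ValueError):
    """Raised when a profile table violates its structural invariants."""


@dataclass
class ProfileTable:
    """Metadata columns plus a numeric feature matrix.

    Parameters
    ----------
    data : DataFrame containing both metadata and feature columns.
    metadata_columns, feature_columns : explicit column partition. The two
        sets must be disjoint and cover only existing columns.
    """

    data: pd.DataFrame
    metadata_columns: list[str]
    feature_columns: list[str]

    def __post_init__(self) -> None:
        self.metadata_columns = list(self.metadata_columns)
        self.feature_columns = list(self.feature_columns)
        cols = set(self.data.columns)
        if len(set(self.data.columns)) != len(self.data.columns):
            raise ProfileTableError("duplicate column names in profile table")
        overlap = set(self.metadata_columns) & set(self.feature_columns)
        if overlap:
            raise ProfileTableError(
                f"columns listed as both metadata and feature: {sorted(overlap)}"
            )
        missing = (set(self.metadata_columns) | set(self.feature_columns)) - cols
        if missing:
            raise ProfileTableError(f"columns not present in table: {sorted(missing)}")
        if not self.feature_columns:
            raise ProfileTableError("no feature columns")

    # -- basic accessors -------------------------------------------------
    @property
    def metadata(self) -> pd.DataFrame:
        return self.data[self.metadata_columns]

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    @property
    def values(self) -> np.ndarray:
        """Feature matrix as a float ndarray (n_profiles, n_features)."""
        return self.features.to_numpy(dtype=float)

    @property
    def n_profiles(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return len(self.feature_columns)

    def select(self, mask: np.ndarray) -> "ProfileTable":
        """Row-subset by boolean mask or integer positions."""
        sub = self.data.iloc[np.asarray(mask).nonzero()[0]] if np.asarray(
            mask
        ).dtype == bool else self.data.iloc[list(mask)]
        return ProfileTable(
            sub.reset_index(drop=True), self.metadata_columns, self.feature_columns
        )

    def validate(self, min_profiles: int = 2) -> "ProfileTable":
        """Check finiteness and minimum size; raise on violation."""
        if self.n_profiles < min_profiles:
            raise ProfileTableError(
                f"table has {self.n_profiles} profiles; at least {min_profiles} required"
            )
        X = self.values
        if not np.isfinite(X).all():
            bad = [
                c
                for c, ok in zip(self.feature_columns, np.isfinite(X).all(axis=0))
                if not ok
            ]
            raise ProfileTableError(f"non-finite values in feature columns: {bad}")
        return self

    # -- I/O -------------------------------------------------------------
    def to_csv(self, path: str | Path, float_format: str = "%.10g") -> None:
        self.data.to_csv(path, index=False, float_format=float_format)

    def to_parquet(self, path: str | Path) -> None:
        self.data.to_parquet(path, index=False)


def _partition_columns(
    df: pd.DataFrame,
    metadata_prefix: str,
    metadata_columns: Sequence[str] | None,
) -> tuple[list[str], list[str]]:
    if metadata_columns is not None:
        meta = list(metadata_columns)
    else:
        meta = [c for c in df.columns if str(c).startswith(metadata_prefix)]
    feats = [c for c in df.columns if c not in set(meta)]
    return meta, feats


def read_profiles(
    path: str | Path,
    metadata_prefix: str = METADATA_PREFIX,
    metadata_columns: Sequence[str] | None = None,
    nan_policy: str = "reject",
    min_profiles: int = 2,
) -> ProfileTable:
    """Read a profile table from CSV or Parquet.

    Metadata columns are identified by ``metadata_prefix`` unless an explicit
    ``metadata_columns`` list is given. ``nan_policy`` controls how feature
    columns containing NaN/Inf are handled: ``"reject"`` (default) raises,
    ``"drop_columns"`` drops the offending columns with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".parquet", ".pq"}:
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    return from_dataframe(
        df,
        metadata_prefix=metadata_prefix,
        metadata_columns=metadata_columns,
        nan_policy=nan_policy,
        min_profiles=min_profiles,
    )


def from_dataframe(
    df: pd.DataFrame,
    metadata_prefix: str = METADATA_PREFIX,
    metadata_columns: Sequence[str] | None = None,
    nan_policy: str = "reject",
    min_profiles: int = 1,
) -> ProfileTable:
    """Build a validated :class:`ProfileTable` from an in-memory DataFrame."""
    if nan_policy not in {"reject", "drop_columns"}:
        raise ValueError(f"unknown nan_policy: {nan_policy!r}")
    if df.columns.duplicated().any():
        dup = sorted(set(df.columns[df.columns.duplicated()]))
        raise ProfileTableError(f"duplicate column names in profile table: {dup}")
    meta, feats = _partition_columns(df, metadata_prefix, metadata_columns)
    if not feats:
        raise ProfileTableError("no feature columns")
    df = df.copy()
    df[feats] = df[feats].apply(pd.to_numeric)
    finite = np.isfinite(df[feats].to_numpy(dtype=float)).all(axis=0)
    if not finite.all():
        bad = [c for c, ok in zip(feats, finite) if not ok]
        if nan_policy == "drop_columns":
            logger.warning(
                "dropping %d feature column(s) with non-finite values: %s",
                len(bad),
                bad,
            )
            feats = [c for c in feats if c not in set(bad)]
            if not feats:
                raise ProfileTableError("no feature columns left after NaN filtering")
            df = df[meta + feats]
        else:
            raise ProfileTableError(f"non-finite values in feature columns: {bad}")
    table = ProfileTable(df.reset_index(drop=True), meta, feats)
    if table.n_profiles < min_profiles:
        raise ProfileTableError(
            f"table has {table.n_profiles} profiles; at least {min_profiles} required"
        )
    return table


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

NORMALIZATION_METHODS = ("standardize", "mad_robustize")


@dataclass(frozen=True)
class NormalizationSpec:
    """How to scale features: z-score or robust (median/MAD) variant.

    ``by`` optionally names a metadata column (typically the plate) within
    whose groups normalization is applied independently. ``epsilon`` guards
    against zero scale in the MAD denominator.
    """

    method: str = "standardize"
    by: str | None = None
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.method not in NORMALIZATION_METHODS:
            raise ValueError(
                f"unknown normalization method {self.method!r}; "
                f"expected one of {NORMALIZATION_METHODS}"
            )
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")


def _normalize_block(X: np.ndarray, method: str, epsilon: float) -> np.ndarray:
    if method == "standardize":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)  # population sd: unit variance of the output
        out = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    else:  # mad_robustize
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0)
        denom = MAD_SCALE * mad + epsilon
        out = np.where(mad > 0, (X - med) / denom, 0.0)
    return out


def normalize(table: ProfileTable, spec: NormalizationSpec) -> ProfileTable:
    """Normalize features per :class:`NormalizationSpec`.

    ``standardize`` centers each feature to mean 0 and scales to unit
    (population) standard deviation; ``mad_robustize`` centers to median 0 and
    divides by the scaled median absolute deviation (constant 1.4826) plus
    ``epsilon``. Applied within each group of ``spec.by`` when given.
    Zero-scale features map to 0.
    """
    if spec.by is not None and spec.by not in table.metadata_columns:
        raise ProfileTableError(f"normalization 'by' column not in metadata: {spec.by!r}")
    df = table.data.copy()
    X = table.values
    if spec.by is None:
        groups: Iterable[np.ndarray] = [np.arange(table.n_profiles)]
    else:
        codes = df[spec.by]
        groups = [np.flatnonzero((codes == v).to_numpy()) for v in codes.unique()]
    out = np.empty_like(X, dtype=float)
    for idx in groups:
        if len(idx) < 2:
            raise ProfileTableError(
                "normalization group with a single profile"
                + ("" if spec.by is None else f" (by={spec.by!r})")
            )
        out[idx] = _normalize_block(X[idx], spec.method, spec.epsilon)
    df[table.feature_columns] = out
    return ProfileTable(df, table.metadata_columns, table.feature_columns)


class ProfileNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer wrapping :func:`normalize`.

    Stateless between fit and transform (scaling parameters are recomputed per
    table, as the per-plate convention requires); ``fit`` only validates.
    """

    def __init__(self, method: str = "standardize", by: str | None = None,
                 epsilon: float = 1e-12):
        self.method = method
        self.by = by
        self.epsilon = epsilon

    def _spec(self) -> NormalizationSpec:
        return NormalizationSpec(method=self.method, by=self.by, epsilon=self.epsilon)

    def fit(self, table: ProfileTable, y=None) -> "ProfileNormalizer":
        self._spec()  # validates parameters
        self.n_features_in_ = table.n_features
        return self

    def transform(self, table: ProfileTable) -> ProfileTable:
        return normalize(table, self._spec())


# ---------------------------------------------------------------------------
# Consensus aggregation
# ---------------------------------------------------------------------------


def consensus(table: ProfileTable, by: Sequence[str]) -> ProfileTable:
    """Aggregate replicate profiles to per-group consensus (feature medians).

    One output row per distinct combination of the ``by`` metadata columns.
    Metadata columns that are not constant within every group are dropped.
    """
    by = list(by)
    if table.n_profiles == 0:
        raise ProfileTableError("empty table")
    missing = set(by) - set(table.metadata_columns)
    if missing:
        raise ProfileTableError(f"'by' columns not in metadata: {sorted(missing)}")
    grouped = table.data.groupby(by, sort=False, dropna=False)
    med = grouped[table.feature_columns].median().reset_index()
    keep_meta = list(by)
    for col in table.metadata_columns:
        if col in by:
            continue
        if (grouped[col].nunique(dropna=False) <= 1).all():
            keep_meta.append(col)
            med[col] = grouped[col].first().reset_index(drop=True)
        else:
            logger.info("consensus: dropping non-constant metadata column %r", col)
    med = med[keep_meta + table.feature_columns]
    return ProfileTable(med, keep_meta, table.feature_columns)
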
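"""Cohort feature matrices: the samples x features table with per-sample metadata.

A behavioral phenotyping run produces, for each animal, a long vector of
numeric features (locomotion, rearing, immobility, startle amplitude, ...)
together with sample metadata: genotype/group, sex, age, treatment and dose.
This module holds the in-memory container for such a cohort, sample selection
by metadata, the missing-value policy, and delimited-text I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Metadata columns recognized by default in a cohort table.
METADATA_COLUMNS = ("group", "sex", "age_months", "treatment", "dose_mg_per_kg")

#: Column holding the unique per-animal identifier.
SAMPLE_ID_COLUMN = "sample_id"

#: Supported missing-value policies.
MISSING_POLICIES = ("drop-feature", "drop-sample", "mean-impute")

Selector = Mapping[str, object] | Callable[[pd.DataFrame], np.ndarray] | np.ndarray


@dataclass
class FeatureMatrix:
    """Samples x features numeric table with per-sample metadata.

    Parameters
    ----------
    sample_ids
        Unique identifier per animal (row order matches ``values``).
    metadata
        One row per sample (index = ``sample_ids``); categorical columns such
        as ``group``, ``sex``, ``treatment`` plus numeric ``age_months`` and
        optional ``dose_mg_per_kg``.
    values
        ``(n_samples, n_features)`` float array; all entries finite.
    feature_names
        Unique, ordered feature names (columns of ``values``).
    """

    sample_ids: list[str]
    metadata: pd.DataFrame
    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f).strip() for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if len(set(self.feature_names)) != len(self.feature_names):
            seen: set[str] = set()
            dupes = sorted({f for f in self.feature_names if f in seen or seen.add(f)})  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate feature names: {dupes}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"values has {self.values.shape[0]} rows but there are "
                f"{len(self.sample_ids)} sample ids"
            )
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but there are "
                f"{len(self.feature_names)} feature names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries after the missing-value policy")
        if not self.metadata.index.equals(pd.Index(self.sample_ids)):
            self.metadata = self.metadata.reindex(self.sample_ids)
            if self.metadata.isna().all(axis=1).any():
                raise ValueError("metadata missing for some sample ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select(self, selector: Selector) -> np.ndarray:
        """Boolean sample mask from a metadata selector.

        The selector is either a mapping ``{metadata column: value or list of
        values}`` (conjunction over columns), a callable on the metadata frame
        returning a boolean vector, or an explicit boolean mask.
        """
        if callable(selector):
            mask = np.asarray(selector(self.metadata), dtype=bool)
        elif isinstance(selector, Mapping):
            mask = np.ones(self.n_samples, dtype=bool)
            for col, wanted in selector.items():
                if col not in self.metadata.columns:
                    raise KeyError(f"unknown metadata column {col!r}")
                column = self.metadata[col]
                if isinstance(wanted, (list, tuple, set, frozenset)):
                    mask &= column.isin(list(wanted)).to_numpy()
                else:
                    mask &= (column == wanted).to_numpy()
        else:
            mask = np.asarray(selector, dtype=bool)
        if mask.shape != (self.n_samples,):
            raise ValueError("selector mask has wrong length")
        return mask

    def subset(self, selector: Selector) -> "FeatureMatrix":
        mask = self.select(selector)
        ids = [s for s, keep in zip(self.sample_ids, mask) if keep]
        return FeatureMatrix(ids, self.metadata.loc[ids], self.values[mask], list(self.feature_names))

    def group_values(self, selector: Selector) -> np.ndarray:
        """Feature values of the selected samples."""
        return self.values[self.select(selector)]

    def to_frame(self) -> pd.DataFrame:
        """Single table: sample_id, metadata columns, then feature columns."""
        frame = self.metadata.copy()
        frame.insert(0, SAMPLE_ID_COLUMN, self.sample_ids)
        feat = pd.DataFrame(self.values, columns=self.feature_names, index=frame.index)
        return pd.concat([frame, feat], axis=1)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def apply_missing_policy(
    values: pd.DataFrame, policy: str, groups: pd.Series | None = None
) -> pd.DataFrame:
    """Resolve missing feature values.

    ``drop-feature`` removes any feature with a missing value; ``drop-sample``
    removes any sample with one; ``mean-impute`` replaces each missing value
    with the mean of its feature within the sample's group (falling back to
    the overall feature mean when the whole group is missing).
    """
    if policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing-value policy {policy!r}; choose from {MISSING_POLICIES}")
    if not values.isna().any().any():
        return values
    if policy == "drop-feature":
        return values.loc[:, values.notna().all(axis=0)]
    if policy == "drop-sample":
        return values.loc[values.notna().all(axis=1)]
    if groups is None:
        return values.fillna(values.mean())
    filled = values.groupby(groups, observed=True).transform(lambda col: col.fillna(col.mean()))
    return filled.fillna(values.mean())


def read_feature_matrix(
    path: str | Path,
    metadata_columns: Sequence[str] | None = None,
    missing_policy: str = "drop-feature",
) -> FeatureMatrix:
    """Read a cohort table from delimited text (TSV or CSV by extension).

    The file must have a header row, a ``sample_id`` column, the declared
    metadata columns (defaults to whichever of :data:`METADATA_COLUMNS` are
    present), and numeric feature columns for everything else.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate column names in {path.name}: {dupes}")
    if SAMPLE_ID_COLUMN not in header:
        raise ValueError(f"{path.name} lacks a {SAMPLE_ID_COLUMN!r} column")

    table = pd.read_csv(
        path, sep=sep, dtype={SAMPLE_ID_COLUMN: str}, float_precision="round_trip"
    )
    if metadata_columns is None:
        metadata_columns = [c for c in METADATA_COLUMNS if c in table.columns]
    else:
        missing = [c for c in metadata_columns if c not in table.columns]
        if missing:
            raise ValueError(f"declared metadata columns absent from {path.name}: {missing}")

    sample_ids = table[SAMPLE_ID_COLUMN].tolist()
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path.name}: {dupes}")
    metadata = table[list(metadata_columns)].copy()
    metadata.index = pd.Index(sample_ids)

    feature_cols = [c for c in table.columns if c != SAMPLE_ID_COLUMN and c not in metadata_columns]
    raw = table[feature_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise ValueError(
            f"non-numeric feature value {raw.iloc[row][feature_cols[col]]!r} at "
            f"sample {sample_ids[row]!r}, feature {feature_cols[col]!r}"
        )
    numeric.index = metadata.index
    group_col = metadata["group"] if "group" in metadata.columns else None
    resolved = apply_missing_policy(numeric, missing_policy, group_col)
    if resolved.shape != numeric.shape:
        n_feat_dropped = numeric.shape[1] - resolved.shape[1]
        n_samp_dropped = numeric.shape[0] - resolved.shape[0]
        warnings.warn(
            f"missing values: dropped {n_feat_dropped} features / {n_samp_dropped} samples "
            f"under policy {missing_policy!r}",
            stacklevel=2,
        )
        if n_samp_dropped:
            keep = resolved.index
            metadata = metadata.loc[keep]
            sample_ids = list(keep)
    return FeatureMatrix(sample_ids, metadata, resolved.to_numpy(dtype=float), list(resolved.columns))


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a cohort table as delimited text (separator from the extension)."""
    path = Path(path)
    # repr of the builtin float is the shortest exact round-trip form
    matrix.to_frame().to_csv(
        path, sep=_sep_for(path), index=False, float_format=lambda x: repr(float(x))
    )
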
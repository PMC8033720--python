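"""Eye-record assembly, normalization, splitting and class balancing.

The working container is a pandas DataFrame with a fixed schema: an
``eye_id`` column, fourteen feature columns (the seven key distances
measured in 2D and again in 3D, millimetres), and a ``label`` column —
the "15 items of data per eye" behind the decision model.  Eyes missing
any distance are screened out at assembly time.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BalanceError, DataError, SplitError
from .morphometry import DISTANCE_NAMES
from .synthcohort import SurgeryLabel, largest_remainder_counts

log = logging.getLogger(__name__)

FEATURE_COLUMNS_2D: tuple[str, ...] = tuple(f"d2_{n}" for n in DISTANCE_NAMES)
FEATURE_COLUMNS_3D: tuple[str, ...] = tuple(f"d3_{n}" for n in DISTANCE_NAMES)
FEATURE_COLUMNS: tuple[str, ...] = FEATURE_COLUMNS_2D + FEATURE_COLUMNS_3D
LABEL_COLUMN = "label"
#: the 15 semantic fields of one eye record (14 features + label)
RECORD_FIELDS: tuple[str, ...] = FEATURE_COLUMNS + (LABEL_COLUMN,)


class FeatureScheme(str, enum.Enum):
    """Which distance block feeds the model: 2D only, 3D only, or both."""

    TWO_D = "2d"
    THREE_D = "3d"
    BOTH = "both"

    @property
    def columns(self) -> tuple[str, ...]:
        if self is FeatureScheme.TWO_D:
            return FEATURE_COLUMNS_2D
        if self is FeatureScheme.THREE_D:
            return FEATURE_COLUMNS_3D
        return FEATURE_COLUMNS


@dataclass(frozen=True)
class SplitConfig:
    """7:3 train/test split, stratified by label, seeded."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise SplitError(f"train_fraction must be in (0, 1), got {self.train_fraction}")


def assemble_records(
    distances_2d: pd.DataFrame,
    distances_3d: pd.DataFrame,
    labels: pd.DataFrame,
) -> pd.DataFrame:
    """Merge per-eye 2D and 3D distances with labels into eye records.

    Inputs carry an ``eye_id`` column plus the seven distance columns
    (either bare names or already ``d2_``/``d3_``-prefixed); ``labels``
    carries ``eye_id`` and ``label``.  Eyes with any missing distance are
    excluded (the screening step); the exclusion count is logged.
    """
    def prefixed(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
        df = df.copy()
        rename = {n: prefix + n for n in DISTANCE_NAMES if n in df.columns}
        df = df.rename(columns=rename)
        want = ["eye_id"] + [prefix + n for n in DISTANCE_NAMES]
        missing = [c for c in want if c not in df.columns]
        if missing:
            raise DataError(f"distance table missing columns {missing}")
        df = df[want]
        return df.assign(eye_id=df["eye_id"].astype(str))

    d2 = prefixed(distances_2d, "d2_")
    d3 = prefixed(distances_3d, "d3_")
    labels = labels.assign(eye_id=labels["eye_id"].astype(str))
    for name, df in (("2D distances", d2), ("3D distances", d3), ("labels", labels)):
        if df["eye_id"].duplicated().any():
            dupes = df.loc[df["eye_id"].duplicated(), "eye_id"].tolist()
            raise DataError(f"duplicate eye_id in {name}: {dupes}")
    if not {"eye_id", LABEL_COLUMN} <= set(labels.columns):
        raise DataError("labels table needs eye_id and label columns")

    merged = d2.merge(d3, on="eye_id", how="outer").merge(
        labels[["eye_id", LABEL_COLUMN]], on="eye_id", how="inner"
    )
    merged[list(FEATURE_COLUMNS)] = merged[list(FEATURE_COLUMNS)].astype(float)
    complete = merged[list(FEATURE_COLUMNS)].notna().all(axis=1) & np.isfinite(
        merged[list(FEATURE_COLUMNS)].fillna(np.nan)
    ).all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        log.info("screening excluded %d eye(s) with incomplete distances", n_excluded)
    out = merged.loc[complete].reset_index(drop=True)
    out[LABEL_COLUMN] = out[LABEL_COLUMN].map(
        lambda v: v.value if isinstance(v, SurgeryLabel) else str(v)
    )
    out.attrs["n_excluded"] = n_excluded
    return out[["eye_id", *RECORD_FIELDS]]


class FeatureNormalizer:
    """Per-feature z-scoring with statistics frozen on the training rows.

    Test rows are always transformed with the stored training mean and
    standard deviation, never their own, so no information leaks from
    test to train.  A zero-variance feature maps to exactly 0 (with a
    warning).
    """

    def __init__(self, columns: tuple[str, ...] = FEATURE_COLUMNS) -> None:
        self.columns = columns
        self.mean_: pd.Series | None = None
        self.std_: pd.Series | None = None
        self._constant: list[str] = []

    def fit(self, train: pd.DataFrame) -> "FeatureNormalizer":
        X = train[list(self.columns)]
        self.mean_ = X.mean()
        std = X.std(ddof=0)
        self._constant = [c for c in self.columns if std[c] == 0]
        if self._constant:
            warnings.warn(
                f"zero-variance feature(s) {self._constant} mapped to 0", stacklevel=2
            )
        self.std_ = std.mask(std == 0, 1.0)
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise DataError("normalizer not fitted")
        out = records.copy()
        out[list(self.columns)] = (records[list(self.columns)] - self.mean_) / self.std_
        for c in self._constant:
            out[c] = 0.0
        return out

    def fit_transform(self, train: pd.DataFrame) -> pd.DataFrame:
        return self.fit(train).transform(train)


def normalize(
    records: pd.DataFrame, stats_from: pd.DataFrame
) -> tuple[pd.DataFrame, FeatureNormalizer]:
    """Z-score ``records`` using statistics computed on ``stats_from``.

    Returns the transformed records and the fitted normalizer for reuse
    on held-out rows.
    """
    norm = FeatureNormalizer().fit(stats_from)
    return norm.transform(records), norm


def split_train_test(
    records: pd.DataFrame, config: SplitConfig = SplitConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic 7:3 (by default) train/test partition.

    The test size is ``round((1 - train_fraction) * n)``; under
    stratification, per-class test counts follow largest-remainder
    rounding of the class shares.  Partitions are disjoint, exhaustive
    and reproducible from the seed.
    """
    config.validate()
    n = len(records)
    if n < 2:
        raise SplitError("need at least 2 records to split")
    n_test = int(round((1.0 - config.train_fraction) * n))
    rng = np.random.default_rng(config.seed)

    if config.stratified:
        test_idx: list[int] = []
        classes = sorted(records[LABEL_COLUMN].unique())
        sizes = [int((records[LABEL_COLUMN] == c).sum()) for c in classes]
        quotas = largest_remainder_counts(n_test, [s / n for s in sizes])
        for c, k in zip(classes, quotas):
            idx = records.index[records[LABEL_COLUMN] == c].to_numpy()
            if len(idx) - k < 1:
                raise SplitError(f"class {c!r} would have no training members")
            test_idx.extend(rng.permutation(idx)[:k].tolist())
        mask = records.index.isin(test_idx)
    else:
        perm = rng.permutation(records.index.to_numpy())
        mask = records.index.isin(perm[:n_test])
    test = records.loc[mask].reset_index(drop=True)
    train = records.loc[~mask].reset_index(drop=True)
    return train, test


def balance_training_set(
    train: pd.DataFrame, seed: int = 0, label_column: str = LABEL_COLUMN
) -> pd.DataFrame:
    """Oversample the minority class (with replacement) to parity.

    Only defined for binary-labeled training rows; rows are never
    removed, and held-out data must never pass through this function.
    """
    classes = sorted(train[label_column].unique())
    if len(classes) != 2:
        raise BalanceError(f"balancing needs exactly 2 classes, got {classes}")
    counts = {c: int((train[label_column] == c).sum()) for c in classes}
    minority = min(classes, key=lambda c: (counts[c], classes.index(c)))
    deficit = max(counts.values()) - counts[minority]
    if deficit == 0:
        return train.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    pool = train.index[train[label_column] == minority].to_numpy()
    extra = rng.choice(pool, size=deficit, replace=True)
    return pd.concat([train, train.loc[extra]], ignore_index=True)
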
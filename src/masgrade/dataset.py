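"""Dataset assembly: fast-stretch selection, splitting, scaling, upsampling.

Datasets are pandas DataFrames in the feature-table schema of
:mod:`masgrade.io` (identifier columns + the 17 feature columns +
``mas_label``).  The canonical training path is::

    select_fast -> exclude_mas4 -> stratified_split -> fit/apply_scaler -> upsample

Only fast stretches carry the catch and are used for classification; MAS 4
rows never enter classifier training (a near-zero range of motion makes the
grade a pure rule); the split is 90:10 stratified by grade; features are
standardised with parameters fitted on the training partition only; random
oversampling (the default) or SMOTE balances the class counts.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from masgrade.features import FEATURE_NAMES
from masgrade.io import MAS_LABELS


def _feature_matrix(df: pd.DataFrame) -> np.ndarray:
    return df[list(FEATURE_NAMES)].to_numpy(dtype=float)


def select_fast(df: pd.DataFrame) -> pd.DataFrame:
    """Keep only fast-stretch rows (the catch appears only at fast speed)."""
    out = df[df["speed"] == "fast"].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("no fast stretches in dataset", stacklevel=2)
    return out

def exclude_mas4(df: pd.DataFrame) -> pd.DataFrame:
    """Drop MAS 4 rows before classifier training (handled by the ROM rule)."""
    mask = df["mas_label"].astype(str) == "4"
    out = df[~mask].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("all rows were MAS 4; dataset is empty", stacklevel=2)
    return out


def _largest_remainder_counts(
    class_counts: dict[str, int], test_frac: float
) -> dict[str, int]:
    """Per-class test-set sizes by largest-remainder allocation.

    Quotas ``n_c * test_frac`` are floored; the leftover seats (to reach the
    rounded overall total) go to the classes with the largest fractional
    remainders, ties broken by MAS order.  Any class with >= 2 rows is then
    guaranteed at least one test row, borrowing from the best-endowed class.
    """
    total = sum(class_counts.values())
    target = int(
        Decimal(total * test_frac).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )
    labels = sorted(class_counts, key=lambda c: MAS_LABELS.index(c) if c in MAS_LABELS else 99)
    quotas = {c: class_counts[c] * test_frac for c in labels}
    counts = {c: int(np.floor(quotas[c])) for c in labels}
    remainders = sorted(
        labels, key=lambda c: (-(quotas[c] - counts[c]), labels.index(c))
    )
    i = 0
    while sum(counts.values()) < target and i < len(remainders):
        c = remainders[i]
        if counts[c] < class_counts[c]:
            counts[c] += 1
        i += 1
    for c in labels:  # every class with >= 2 rows gets a test row
        if class_counts[c] >= 2 and counts[c] == 0:
            donor = max(labels, key=lambda d: counts[d])
            if counts[donor] > 1:
                counts[donor] -= 1
            counts[c] = 1
        if class_counts[c] == 1:
            warnings.warn(
                f"class {c!r} has a single row; kept in the training set",
                stacklevel=3,
            )
            counts[c] = 0
    return counts


def stratified_split(
    df: pd.DataFrame, test_frac: float = 0.1, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split with largest-remainder class allocation.

    Deterministic given ``seed``; the partitions are disjoint by row.
    Splitting is by stretch-row; see :func:`grouped_split` for a stricter
    subject-grouped variant.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    labels = df["mas_label"].astype(str)
    class_counts = labels.value_counts().to_dict()
    test_counts = _largest_remainder_counts(class_counts, test_frac)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for label, n_test in test_counts.items():
        rows = np.flatnonzero(labels.to_numpy() == label)
        chosen = rng.choice(rows, size=n_test, replace=False)
        test_idx.extend(int(i) for i in chosen)
    test_mask = np.zeros(len(df), dtype=bool)
    test_mask[test_idx] = True
    train = df[~test_mask].reset_index(drop=True)
    test = df[test_mask].reset_index(drop=True)
    return train, test


def grouped_split(
    df: pd.DataFrame, test_frac: float = 0.1, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split by subject so no subject appears in both partitions.

    Stricter than the row-level split (no within-subject leakage), at the
    cost of looser control over per-class test counts.
    """
    rng = np.random.default_rng(seed)
    subjects = df["subject_id"].unique()
    rng.shuffle(subjects)
    n_test = max(1, int(round(test_frac * len(subjects))))
    test_subjects = set(subjects[:n_test])
    mask = df["subject_id"].isin(test_subjects)
    return df[~mask].reset_index(drop=True), df[mask].reset_index(drop=True)


@dataclasses.dataclass
class ScalerParams:
    """Per-feature standardisation parameters, fitted on the train partition."""

    mean: dict[str, float]
    std: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            name: {"mean": self.mean[name], "std": self.std[name]}
            for name in self.mean
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            mean={k: v["mean"] for k, v in payload.items()},
            std={k: v["std"] for k, v in payload.items()},
        )


def fit_scaler(train: pd.DataFrame) -> ScalerParams:
    """Fit mean/std per feature (population std, matching standard scaling).

    A constant feature gets std 1 (with a warning) so scaling stays defined.
    """
    X = _feature_matrix(train)
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # ddof=0
    constant = std <= 0
    if constant.any():
        names = [FEATURE_NAMES[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant feature(s) {names}; std set to 1", stacklevel=2)
        std = np.where(constant, 1.0, std)
    return ScalerParams(
        mean=dict(zip(FEATURE_NAMES, mean.tolist())),
        std=dict(zip(FEATURE_NAMES, std.tolist())),
    )


def apply_scaler(params: ScalerParams, df: pd.DataFrame) -> pd.DataFrame:
    """Standardise the feature columns with previously fitted parameters."""
    out = df.copy()
    for name in FEATURE_NAMES:
        out[name] = (out[name] - params.mean[name]) / params.std[name]
    return out


def _class_rows(df: pd.DataFrame) -> dict[str, np.ndarray]:
    labels = df["mas_label"].astype(str).to_numpy()
    classes = sorted(set(labels), key=lambda c: MAS_LABELS.index(c) if c in MAS_LABELS else 99)
    rows = {c: np.flatnonzero(labels == c) for c in classes}
    for c, r in rows.items():
        if len(r) == 0:
            raise ValueError(f"class {c!r} has no rows")
    return rows


def ros_upsample(train: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Random oversampling: duplicate minority rows until all classes match
    the majority count.  Only exact duplicates are added."""
    rows = _class_rows(train)
    majority = max(len(r) for r in rows.values())
    rng = np.random.default_rng(seed)
    extra_idx: list[int] = []
    for c, r in rows.items():
        deficit = majority - len(r)
        if deficit > 0:
            extra_idx.extend(int(i) for i in rng.choice(r, size=deficit, replace=True))
    if not extra_idx:
        return train.reset_index(drop=True)
    out = pd.concat([train, train.iloc[extra_idx]], ignore_index=True)
    return out


def smote_upsample(
    train: pd.DataFrame, k_neighbors: int = 5, seed: int = 0
) -> pd.DataFrame:
    """SMOTE: synthesise minority rows on segments between same-class neighbours.

    Each synthetic row is ``x + u * (x_nn - x)`` for a random same-class
    sample ``x``, one of its ``k_neighbors`` nearest same-class neighbours
    ``x_nn`` and ``u ~ U(0, 1)``.  Classes with too few rows get a reduced
    ``k`` with a warning.  Identifier columns are copied from the base row.
    """
    rows = _class_rows(train)
    majority = max(len(r) for r in rows.values())
    rng = np.random.default_rng(seed)
    X = _feature_matrix(train)
    new_frames: list[pd.DataFrame] = []
    for c, r in rows.items():
        deficit = majority - len(r)
        if deficit == 0:
            continue
        k = k_neighbors
        if len(r) <= k:
            k = max(1, len(r) - 1)
            warnings.warn(
                f"class {c!r} has {len(r)} rows; SMOTE k reduced to {k}",
                stacklevel=2,
            )
        if k == 0:
            raise ValueError(f"class {c!r} has a single row; SMOTE undefined")
        Xc = X[r]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, neigh = nn.kneighbors(Xc)
        base = rng.integers(0, len(r), size=deficit)
        pick = rng.integers(1, k + 1, size=deficit)  # skip self (column 0)
        gap = rng.random(deficit)
        synth = Xc[base] + gap[:, None] * (Xc[neigh[base, pick]] - Xc[base])
        frame = train.iloc[r[base]].copy().reset_index(drop=True)
        frame[list(FEATURE_NAMES)] = synth
        new_frames.append(frame)
    if not new_frames:
        return train.reset_index(drop=True)
    return pd.concat([train, *new_frames], ignore_index=True)
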
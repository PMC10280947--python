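"""Deterministic cleaning, encoding, standardization and splitting.

One encoding dialect is shared by the GAN and the classifier bench:
categorical variables become blocks of 0/1 indicator columns (a full
indicator set by default, so that decoding is an arg-max over the block, or
drop-first for identifiable regression designs) and numeric variables are
z-standardized.  The fitted parameters live in an :class:`EncodingMap` so a
map estimated on training rows can be applied to held-out rows without
leakage.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import SITES, GENDERS, AGE_MIN, AGE_MAX

log = logging.getLogger(__name__)

#: default variable roles for a cohort table (outcome is a label, not a feature)
NUMERIC_VARS = ("age", "ecog", "n_televisits")
CATEGORICAL_VARS = ("gender", "site", "metastatic", "bone_mets", "btcp", "neuropathic", "med_gt60")

_KNOWN_LEVELS = {
    "gender": list(GENDERS),
    "site": list(SITES),
    "metastatic": [0, 1],
    "bone_mets": [0, 1],
    "btcp": [0, 1],
    "neuropathic": [0, 1],
    "med_gt60": [0, 1],
}

_INT_BOUNDS = {"age": (AGE_MIN, AGE_MAX), "ecog": (0, 4), "n_televisits": (1, 50)}


@dataclass
class EncodingMap:
    """Per-variable encoding scheme: one-hot levels or (mean, sd) z-parameters."""

    numeric: dict = field(default_factory=dict)  # var -> (mean, sd)
    categorical: dict = field(default_factory=dict)  # var -> ordered levels
    drop_first: bool = False

    @property
    def columns(self) -> list[str]:
        cols = [f"{v}" for v in self.numeric]
        for var, levels in self.categorical.items():
            used = levels[1:] if self.drop_first else levels
            cols.extend(f"{var}={lev}" for lev in used)
        return cols

    @property
    def width(self) -> int:
        return len(self.columns)

    def block_slices(self) -> dict:
        """Column index range of each variable in the encoded matrix."""
        out, i = {}, 0
        for v in self.numeric:
            out[v] = slice(i, i + 1)
            i += 1
        for var, levels in self.categorical.items():
            k = len(levels) - 1 if self.drop_first else len(levels)
            out[var] = slice(i, i + k)
            i += k
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "numeric": {k: list(v) for k, v in self.numeric.items()},
                    "categorical": self.categorical,
                    "drop_first": self.drop_first,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "EncodingMap":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            numeric={k: tuple(v) for k, v in d["numeric"].items()},
            categorical=d["categorical"],
            drop_first=d["drop_first"],
        )


def fit_encoding(
    cohort: pd.DataFrame,
    numeric=NUMERIC_VARS,
    categorical=CATEGORICAL_VARS,
    drop_first: bool = False,
) -> EncodingMap:
    """Estimate standardization parameters and level sets from a cohort."""
    if len(cohort) == 0:
        raise ValueError("cannot fit an encoding on an empty cohort")
    emap = EncodingMap(drop_first=drop_first)
    for var in numeric:
        x = cohort[var].to_numpy(float)
        sd = float(x.std(ddof=0))
        if sd <= 0:
            log.warning("zero-variance numeric column %r; sd fallback to 1", var)
            sd = 1.0
        emap.numeric[var] = (float(x.mean()), sd)
    for var in categorical:
        emap.categorical[var] = list(_KNOWN_LEVELS.get(var, sorted(cohort[var].unique())))
    return emap


def encode(cohort: pd.DataFrame, emap: EncodingMap | None = None, **fit_kw):
    """Encode a cohort into a numeric matrix; returns ``(matrix, map)``.

    When ``emap`` is omitted it is fit on the cohort itself, in which case
    the standardized numeric columns have mean 0 and sd 1 (up to the
    zero-variance guard).
    """
    if len(cohort) == 0:
        raise ValueError("cannot encode an empty cohort")
    if emap is None:
        emap = fit_encoding(cohort, **fit_kw)
    n = len(cohort)
    blocks = []
    for var, (mean, sd) in emap.numeric.items():
        blocks.append(((cohort[var].to_numpy(float) - mean) / sd)[:, None])
    for var, levels in emap.categorical.items():
        vals = cohort[var].to_numpy()
        idx = np.full(n, -1, dtype=int)
        for j, lev in enumerate(levels):
            idx[vals == lev] = j
        if (idx < 0).any():
            bad = vals[idx < 0][0]
            raise ValueError(f"unseen category for variable {var!r}: {bad!r}")
        hot = np.eye(len(levels))[idx]
        blocks.append(hot[:, 1:] if emap.drop_first else hot)
    return np.hstack(blocks), emap


def decode(matrix: np.ndarray, emap: EncodingMap) -> pd.DataFrame:
    """Invert :func:`encode`: arg-max per categorical block, de-standardize
    numerics, round integer-valued variables to their clinical range."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[1] != emap.width:
        raise ValueError(
            f"matrix width {matrix.shape[1] if matrix.ndim == 2 else '?'} "
            f"does not match encoding width {emap.width}"
        )
    out = {}
    slices = emap.block_slices()
    for var, (mean, sd) in emap.numeric.items():
        x = matrix[:, slices[var]].ravel() * sd + mean
        lo, hi = _INT_BOUNDS.get(var, (None, None))
        if lo is not None:
            x = np.clip(np.rint(x), lo, hi).astype(int)
        out[var] = x
    for var, levels in emap.categorical.items():
        block = matrix[:, slices[var]]
        if emap.drop_first:
            block = np.hstack([1.0 - block.sum(axis=1, keepdims=True), block])
        out[var] = np.asarray(levels, dtype=object)[block.argmax(axis=1)]
    df = pd.DataFrame(out)
    for var in emap.categorical:
        if set(_KNOWN_LEVELS.get(var, [])) == {0, 1}:
            df[var] = df[var].astype(int)
    return df


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    test: np.ndarray
    ratio: float
    seed: int


def split(n: int, ratio: float, seed: int) -> SplitIndices:
    """Uniformly random train/test split; |train| = floor(ratio * n),
    remainder to the test set.  Deterministic per seed."""
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly between 0 and 1")
    perm = np.random.default_rng(seed).permutation(n)
    k = int(np.floor(ratio * n))
    return SplitIndices(train=np.sort(perm[:k]), test=np.sort(perm[k:]), ratio=ratio, seed=seed)
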
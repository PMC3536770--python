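"""Single-channel cDNA-array normalization.

Radioactive spotted arrays report one intensity per spot (Si) together with a
vector-oligonucleotide signal (Vi) that measures how much cDNA was actually
deposited in the spot.  The normalization chain is:

1. spotted-cDNA correction:  (Si / Vi) * median over arrays of Vi
2. removal of non-informative clones (too little spotted cDNA)
3. log2 transform (floored to avoid -inf)
4. quantile normalization across arrays

Steps are exposed individually and as :func:`normalize_chain`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidConfigError

logger = logging.getLogger(__name__)

#: canonical treatment-group names of the study design
GROUP_NAMES = ("control", "T1d7", "T2d7", "T2d14", "KTd7")


@dataclass
class SignalMatrix:
    """Raw per-spot signals for one hybridization series.

    Attributes
    ----------
    S : DataFrame, clone x sample
        Raw spot signal (intensity units, >= 0).
    V : DataFrame, clone x sample
        Vector-oligo signal measuring spotted cDNA (> 0 where informative).
    B : Series, per sample
        Scalar background level of each array (> 0).
    groups : Series, per sample
        Treatment-group label of each array.
    """

    S: pd.DataFrame
    V: pd.DataFrame
    B: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if not self.S.shape == self.V.shape:
            raise InvalidConfigError("S and V must share dimensions")
        if not (self.S.index.equals(self.V.index) and self.S.columns.equals(self.V.columns)):
            raise InvalidConfigError("S and V must share clone and sample labels")
        if len(self.B) != self.S.shape[1]:
            raise InvalidConfigError("B must have one entry per sample")
        missing = set(self.S.columns) - set(self.groups.index)
        if missing:
            raise InvalidConfigError(f"samples without group label: {sorted(missing)}")

    @property
    def clone_ids(self) -> pd.Index:
        return self.S.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.S.columns

    def subset_clones(self, keep: pd.Index | np.ndarray) -> "SignalMatrix":
        return SignalMatrix(self.S.loc[keep], self.V.loc[keep], self.B, self.groups)


@dataclass
class ExpressionMatrix:
    """Normalized log2 expression values with a record of applied transforms."""

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def clone_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def correct_for_spotted_cdna(sig: SignalMatrix) -> pd.DataFrame:
    """Correct each spot for the amount of spotted cDNA.

    output[c, a] = (S[c, a] / V[c, a]) * median_{a'} V[c, a']

    The median is taken over all arrays, including the spot's own.
    """
    bad = (sig.V <= 0).any(axis=1)
    if bad.any():
        clone = sig.V.index[bad.to_numpy()][0]
        raise DegenerateInputError(f"non-positive vector signal for clone {clone!r}")
    med_v = sig.V.median(axis=1)
    return sig.S.div(sig.V).mul(med_v, axis=0)


def filter_noninformative(
    sig: SignalMatrix, multiple: float = 3.0, frac: float = 0.20
) -> pd.Series:
    """Keep-mask over clones: drop clones with too little spotted cDNA.

    A clone is removed iff V < multiple * background in strictly more than
    ``frac`` of the samples.
    """
    if not 0.0 <= frac <= 1.0:
        raise InvalidConfigError(f"frac must be in [0, 1], got {frac}")
    if (sig.B <= 0).any():
        raise DegenerateInputError("background must be positive")
    below = sig.V.lt(multiple * sig.B, axis=1)
    n = sig.V.shape[1]
    keep = ~(below.sum(axis=1) > frac * n)
    keep.name = "keep"
    return keep


def log2_transform(corrected: pd.DataFrame, floor: float | None = None) -> pd.DataFrame:
    """log2 with a positive floor.

    Values <= ``floor`` are raised to ``floor`` first.  By default the floor is
    the smallest strictly positive value of the matrix, which avoids -inf
    without inventing an intensity unit.
    """
    arr = corrected.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise DegenerateInputError("corrected matrix contains non-finite values")
    if floor is None:
        positive = arr[arr > 0]
        if positive.size == 0:
            raise DegenerateInputError("no positive values to derive a log2 floor from")
        floor = float(positive.min())
    if floor <= 0:
        raise InvalidConfigError("floor must be positive")
    return pd.DataFrame(
        np.log2(np.maximum(arr, floor)), index=corrected.index, columns=corrected.columns
    )


def quantile_normalize(m: pd.DataFrame) -> ExpressionMatrix:
    """Quantile normalization across columns (arrays).

    Each column's k-th order statistic is replaced by the mean of the k-th
    order statistics over all columns; within-column rank order is preserved
    and ties receive the mean of the reference values at their tied ranks.
    """
    if m.isna().to_numpy().any():
        raise DegenerateInputError("quantile normalization requires complete data")
    if m.shape[1] < 2:
        logger.info("quantile_normalize: single column, returned unchanged")
        return ExpressionMatrix(m.copy(), provenance=["quantile (no-op, single column)"])
    arr = m.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = reference
        # ties: average the reference values assigned to equal input values
        mapped = pd.Series(mapped).groupby(pd.Series(col)).transform("mean").to_numpy()
        out[:, j] = mapped
    return pd.DataFrame(out, index=m.index, columns=m.columns).pipe(
        lambda df: ExpressionMatrix(df, provenance=["quantile"])
    )


def normalize_chain(
    sig: SignalMatrix,
    multiple: float = 3.0,
    frac: float = 0.20,
    floor: float | None = None,
) -> ExpressionMatrix:
    """Full chain: filter -> spotted-cDNA correction -> log2 -> quantile.

    The filter uses only V and B, so filtering before or after the correction
    yields the same kept set; it is applied first to avoid correcting spots
    that are discarded anyway.
    """
    keep = filter_noninformative(sig, multiple=multiple, frac=frac)
    n_removed = int((~keep).sum())
    logger.info("filter_noninformative: removed %d of %d clones", n_removed, len(keep))
    kept = sig.subset_clones(keep[keep].index)
    corrected = correct_for_spotted_cdna(kept)
    logged = log2_transform(corrected, floor=floor)
    expr = quantile_normalize(logged)
    expr.provenance = [
        f"filter_noninformative(multiple={multiple}, frac={frac})",
        "correct_for_spotted_cdna",
        "log2",
    ] + expr.provenance
    return expr
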
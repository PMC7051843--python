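"""Attribute-profile lattice and Q-matrix handling.

A diagnostic classification model (DCM) with K binary symptoms has a latent
space of 2**K *attribute profiles* alpha = (alpha_1, ..., alpha_K), one latent
class per profile.  Profiles are ordered by binary counting with symptom 1 as
the most significant bit::

    index(alpha) = sum_k alpha_k * 2**(K - 1 - k)      (k zero-based)

so index 0 is the all-zero profile, index 2**K - 1 the all-one profile, and
reading a profile left to right matches reading the symptom labels C1..CK left
to right.  Every module in this package uses this ordering.

The Q-matrix is the J x K binary incidence matrix with q_jk = 1 when item j
measures symptom k.  An item's *reduced profile* is the sub-vector of a
profile restricted to the symptoms that item measures (in Q-matrix column
order); the item response function depends on the profile only through it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import comb

__all__ = [
    "QMatrix",
    "ValidationReport",
    "enumerate_profiles",
    "profile_to_index",
    "index_to_profile",
    "reduce_profile",
    "count_profiles_with_min_symptoms",
    "validate_qmatrix",
    "default_symptom_ids",
]

MAX_K = 16


def default_symptom_ids(K: int) -> list[str]:
    """C1..CK labels, the convention for the nine DSM-V SPD criteria."""
    return [f"C{k + 1}" for k in range(K)]


def _check_k(K: int) -> None:
    if not (1 <= int(K) <= MAX_K):
        raise ValueError(f"K must be in [1, {MAX_K}], got {K}")


def enumerate_profiles(K: int) -> np.ndarray:
    """All 2**K attribute profiles in lattice order.

    Returns an int8 array of shape (2**K, K); row i is the profile with
    index i under the most-significant-bit-first ordering.
    """
    _check_k(K)
    idx = np.arange(2**K)
    shifts = K - 1 - np.arange(K)
    return ((idx[:, None] >> shifts[None, :]) & 1).astype(np.int8)


def profile_to_index(alpha: np.ndarray) -> int:
    """Lattice index of a binary profile (symptom 1 = most significant bit)."""
    alpha = np.asarray(alpha)
    K = alpha.shape[-1]
    _check_k(K)
    weights = 1 << (K - 1 - np.arange(K))
    return int(alpha @ weights) if alpha.ndim == 1 else alpha @ weights


def index_to_profile(index: int, K: int) -> np.ndarray:
    """Inverse of :func:`profile_to_index`."""
    _check_k(K)
    if not (0 <= index < 2**K):
        raise ValueError(f"index {index} out of range for K={K}")
    shifts = K - 1 - np.arange(K)
    return ((index >> shifts) & 1).astype(np.int8)


def reduce_profile(alpha: np.ndarray, q_row: np.ndarray) -> np.ndarray:
    """Restrict a profile to the symptoms an item measures.

    Returns the sub-vector of ``alpha`` at the positions where ``q_row`` is 1,
    preserving Q-matrix column order.
    """
    alpha = np.asarray(alpha)
    q_row = np.asarray(q_row)
    if alpha.shape != q_row.shape:
        raise ValueError(f"profile shape {alpha.shape} != q_row shape {q_row.shape}")
    if not q_row.any():
        raise ValueError("q_row has no 1s: item measures no symptom")
    return alpha[q_row.astype(bool)]


def count_profiles_with_min_symptoms(K: int, m: int) -> int:
    """Number of length-K binary profiles with at least m ones.

    Equals sum_{s=m}^{K} C(K, s); for K=9, m=5 this is the 256 profiles that
    satisfy the DSM-V five-or-more-symptoms rule.
    """
    _check_k(K)
    if not (0 <= m <= K):
        raise ValueError(f"m must be in [0, K={K}], got {m}")
    return int(sum(comb(K, s, exact=True) for s in range(m, K + 1)))


@dataclass(frozen=True)
class QMatrix:
    """Items x symptoms binary incidence matrix with row/column labels."""

    q: np.ndarray
    item_ids: tuple[str, ...] = ()
    symptom_ids: tuple[str, ...] = ()

    def __post_init__(self):
        q = np.asarray(self.q)
        if q.ndim != 2:
            raise ValueError("Q-matrix must be 2-dimensional")
        if not np.isin(q, (0, 1)).all():
            raise ValueError("Q-matrix entries must be 0 or 1")
        object.__setattr__(self, "q", q.astype(np.int8))
        item_ids = tuple(self.item_ids) or tuple(
            str(j + 1) for j in range(q.shape[0])
        )
        symptom_ids = tuple(self.symptom_ids) or tuple(
            default_symptom_ids(q.shape[1])
        )
        if len(item_ids) != q.shape[0]:
            raise ValueError("item_ids length does not match Q-matrix rows")
        if len(symptom_ids) != q.shape[1]:
            raise ValueError("symptom_ids length does not match Q-matrix columns")
        object.__setattr__(self, "item_ids", item_ids)
        object.__setattr__(self, "symptom_ids", symptom_ids)

    @property
    def n_items(self) -> int:
        return self.q.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.q.shape[1]

    def item_attrs(self, j: int) -> np.ndarray:
        """Column indices of the symptoms measured by item j (row order)."""
        return np.flatnonzero(self.q[j])

    def items_per_symptom(self) -> pd.Series:
        """How many items measure each symptom (Q-matrix column sums)."""
        return pd.Series(self.q.sum(axis=0), index=list(self.symptom_ids))

    def subset(self, item_ids: list[str]) -> "QMatrix":
        """Row-subset keeping symptom columns (possibly empty) intact."""
        pos = [self.item_ids.index(i) for i in item_ids]
        return QMatrix(self.q[pos], tuple(item_ids), self.symptom_ids)

    def drop_symptoms(self, symptom_ids: list[str]) -> "QMatrix":
        keep = [k for k, s in enumerate(self.symptom_ids) if s not in symptom_ids]
        return QMatrix(
            self.q[:, keep],
            self.item_ids,
            tuple(self.symptom_ids[k] for k in keep),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.q, index=list(self.item_ids), columns=list(self.symptom_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "QMatrix":
        return cls(
            df.to_numpy(),
            tuple(str(i) for i in df.index),
            tuple(str(c) for c in df.columns),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="item")

    @classmethod
    def from_csv(cls, path: str | Path) -> "QMatrix":
        df = pd.read_csv(path, index_col=0, comment="#")
        return cls.from_dataframe(df)


@dataclass
class ValidationReport:
    """Report-only Q-matrix check: errors block calibration, warnings do not."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_qmatrix(Q: QMatrix) -> ValidationReport:
    """Check a Q-matrix for structural problems.

    All-zero rows are errors (an item must measure something); all-zero
    columns are warnings (a symptom no item measures cannot be estimated);
    multi-attribute rows are flagged as informational warnings only, since
    the general G-DINA model supports them.
    """
    report = ValidationReport()
    row_sums = Q.q.sum(axis=1)
    for j in np.flatnonzero(row_sums == 0):
        report.errors.append(f"item {Q.item_ids[j]}: row is all zeros")
    col_sums = Q.q.sum(axis=0)
    for k in np.flatnonzero(col_sums == 0):
        report.warnings.append(
            f"symptom {Q.symptom_ids[k]}: measured by no item"
        )
    multi = np.flatnonzero(row_sums > 1)
    if multi.size:
        ids = ", ".join(Q.item_ids[j] for j in multi)
        report.warnings.append(f"multi-attribute rows (supported): {ids}")
    return report
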
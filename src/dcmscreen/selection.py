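"""Item selection: apply retention rules and rebuild the reduced instrument.

An item is excluded when its discrimination falls below ``disc_min``
(default 0.30), its S-X² fit p-value falls below ``fit_alpha`` (default
.01), or its Wald DIF p-value falls below ``dif_alpha`` (default .01).  All
inequalities are strict, so an item sitting exactly on a threshold is
retained.  Items with a missing (not-computable) statistic for an applied
rule are excluded as not evaluable.  Selection is a single pass over
diagnostics computed on the full-scale calibration; the retained items are
then recalibrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import compute_item_diagnostics
from .gdina import CalibrationResult, FitOptions, fit_em
from .profiles import QMatrix

__all__ = ["SelectionThresholds", "SelectionResult", "select_items",
           "reduce_qmatrix", "build_reduced_instrument"]

LOW_DISC = "LOW_DISC"
DIF = "DIF"
MISFIT = "MISFIT"
NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class SelectionThresholds:
    """Exclusion rules: disc < disc_min, S-X² p < fit_alpha, DIF p < dif_alpha."""

    disc_min: float = 0.30
    fit_alpha: float = 0.01
    dif_alpha: float = 0.01

    def __post_init__(self):
        if not (0 < self.disc_min < 1):
            raise ValueError("disc_min must be in (0, 1)")
        for a in (self.fit_alpha, self.dif_alpha):
            if not (0 < a < 1):
                raise ValueError("alpha levels must be in (0, 1)")


@dataclass
class SelectionResult:
    retained: list[str]
    excluded: dict[str, list[str]]  # item id -> reason codes
    diagnostics: pd.DataFrame
    reduced_q: QMatrix | None = None
    recalibration: CalibrationResult | None = None
    dropped_symptoms: list[str] = field(default_factory=list)


def select_items(
    diagnostics: pd.DataFrame, thresholds: SelectionThresholds | None = None
) -> SelectionResult:
    """Partition items into retained and excluded with per-item reason codes.

    ``diagnostics`` needs columns ``item`` and ``disc``; ``sx2_p`` and
    ``wald_p`` trigger their rules only when present (a pipeline run without
    a group covariate has no DIF column and skips that rule).
    """
    thr = thresholds or SelectionThresholds()
    retained: list[str] = []
    excluded: dict[str, list[str]] = {}
    have_fit = "sx2_p" in diagnostics.columns
    have_dif = "wald_p" in diagnostics.columns
    for row in diagnostics.itertuples(index=False):
        reasons = []
        checks = [("disc", LOW_DISC, lambda v: v < thr.disc_min)]
        if have_fit:
            checks.append(("sx2_p", MISFIT, lambda v: v < thr.fit_alpha))
        if have_dif:
            checks.append(("wald_p", DIF, lambda v: v < thr.dif_alpha))
        for col, code, rule in checks:
            v = getattr(row, col)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                if NOT_EVALUABLE not in reasons:
                    reasons.append(NOT_EVALUABLE)
            elif rule(v):
                reasons.append(code)
        if reasons:
            excluded[row.item] = reasons
        else:
            retained.append(row.item)
    return SelectionResult(retained=retained, excluded=excluded,
                           diagnostics=diagnostics)


def reduce_qmatrix(Q: QMatrix, retained: list[str]) -> tuple[QMatrix, list[str]]:
    """Row-subset the Q-matrix to the retained items, dropping (with a loud
    warning) any symptom column left with no item; returns the reduced
    Q-matrix and the dropped symptom ids."""
    reduced_q = Q.subset(retained)
    per_symptom = reduced_q.items_per_symptom()
    dropped = [s for s, n in per_symptom.items() if n == 0]
    if dropped:
        warnings.warn(
            f"symptoms with no retained item dropped from the instrument: {dropped}"
        )
        reduced_q = reduced_q.drop_symptoms(dropped)
    return reduced_q, dropped


def build_reduced_instrument(
    X,
    Q: QMatrix,
    thresholds: SelectionThresholds | None = None,
    group: np.ndarray | None = None,
    options: FitOptions | None = None,
    collapse_min: float = 1.0,
) -> SelectionResult:
    """Full pipeline: calibrate, diagnose, select, recalibrate.

    Symptom columns left with no retained item are dropped from the reduced
    Q-matrix with a loud warning (the reduced instrument then measures fewer
    criteria).
    """
    X = np.asarray(X, dtype=float)
    full = fit_em(X, Q, options=options, group=group)
    diag = compute_item_diagnostics(
        full, X, group=group, collapse_min=collapse_min, options=options
    )
    sel = select_items(diag, thresholds)
    if not sel.retained:
        raise ValueError("no items retained; thresholds exclude the whole scale")

    keep_pos = [Q.item_ids.index(i) for i in sel.retained]
    reduced_q, dropped = reduce_qmatrix(Q, sel.retained)
    sel.dropped_symptoms = dropped
    sel.reduced_q = reduced_q
    sel.recalibration = fit_em(X[:, keep_pos], reduced_q, options=options)
    return sel
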
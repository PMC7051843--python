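"""Per-item psychometric diagnostics and reliability indices.

Three statistics drive item selection:

* **Discrimination** Disc_j = P(X_j=1 | all required symptoms present)
  - P(X_j=1 | none present), the endorsement-probability gap between
  full-mastery and zero-mastery reduced profiles.
* **S-X² item fit** (Orlando-Thissen style): observed vs model-implied
  endorsement proportions across total-score groups, with the score
  distribution obtained by convolving item response probabilities over the
  latent-class mixture and the studied item held out of the rest-score.
  Adjacent score groups are collapsed until every expected cell reaches a
  minimum count; the statistic is referred to chi-square with
  df = (#groups - #item parameters).
* **Wald DIF**: the studied item gets group-specific parameters in a joint
  calibration anchored by all other items; the Wald statistic contrasts the
  two delta vectors using the sum of per-group outer-product-of-gradients
  covariances, df = number of item parameters (2 for single-attribute
  items).

Reliability: per-symptom classification consistency (expected agreement of
two independent classifications drawn from each respondent's posterior) and
the classical Guttman split-half coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .gdina import (
    CalibrationResult,
    FitOptions,
    ItemParams,
    _check_responses,
    _class_prob_matrix,
    _reduced_index,
    fit_em,
)
from .profiles import QMatrix

__all__ = [
    "discrimination",
    "s_x2_item_fit",
    "wald_dif",
    "wald_dif_all",
    "classification_consistency",
    "guttman_split_half",
    "compute_item_diagnostics",
    "ReliabilityReport",
]


def discrimination(params: ItemParams) -> float:
    """Disc_j: full-mastery minus zero-mastery endorsement probability."""
    return params.discrimination


# ---------------------------------------------------------------------------
# S-X² item fit
# ---------------------------------------------------------------------------


def _score_distribution(P: np.ndarray) -> np.ndarray:
    """Total-score distribution per class by forward convolution.

    P is (J, L); returns (L, J+1) with f[l, s] = P(total score = s | class l).
    """
    J, L = P.shape
    f = np.zeros((L, J + 1))
    f[:, 0] = 1.0
    for j in range(J):
        p = P[j][:, None]
        new = f * (1.0 - p)
        new[:, 1:] += f[:, :-1] * p
        f = new
    return f


def s_x2_item_fit(
    result: CalibrationResult, X, collapse_min: float = 1.0
) -> pd.DataFrame:
    """S-X² statistic, df and p-value per item.

    Requires complete responses (the total score is undefined otherwise);
    respondents with any missing response are dropped.  Items where fewer
    than two score groups survive collapsing, or df <= 0, are marked not
    computable (NaN statistic).
    """
    X = _check_responses(X)
    complete = ~np.isnan(X).any(axis=1)
    X = X[complete].astype(int)
    N, J = X.shape
    Q = result.qmatrix
    nu = result.class_dist
    rindex = _reduced_index(Q)
    probs = [ip.probs for ip in result.item_params]
    Pmat = _class_prob_matrix(probs, rindex)  # (J, L)

    scores = X.sum(axis=1)
    n_s = np.bincount(scores, minlength=J + 1).astype(float)
    obs_endorse = np.array(
        [[X[scores == s, j].sum() for s in range(J + 1)] for j in range(J)],
        dtype=float,
    )

    f_all = _score_distribution(Pmat)  # (L, J+1)
    denom = nu @ f_all  # marginal score distribution

    rows = []
    for j in range(J):
        keep = np.arange(J) != j
        f_mj = _score_distribution(Pmat[keep])  # (L, J)
        # E[endorse | total score s] for s = 1..J; rest-score is s-1
        num = nu @ (Pmat[j][:, None] * f_mj)  # (J,) indexed by s-1
        with np.errstate(invalid="ignore", divide="ignore"):
            E = np.where(denom[1:] > 0, num / denom[1:], 0.0)
        # scores 0 and J are deterministic for every item; fold them via collapsing
        stat, dfree, n_groups = _collapsed_chi2(
            n_counts=n_s[1:],
            obs_counts=obs_endorse[j, 1:],
            expected_rate=E,
            collapse_min=collapse_min,
            n_params=result.item_params[j].deltas.shape[0],
        )
        if stat is None:
            rows.append((Q.item_ids[j], np.nan, 0, np.nan, n_groups))
        else:
            p = float(chi2.sf(stat, dfree))
            rows.append((Q.item_ids[j], stat, dfree, p, n_groups))
    return pd.DataFrame(
        rows, columns=["item", "sx2", "sx2_df", "sx2_p", "sx2_groups"]
    )


def _collapsed_chi2(n_counts, obs_counts, expected_rate, collapse_min, n_params):
    """Greedy adjacent collapsing then Pearson X² over score groups."""
    groups = []  # (n, obs_endorse, exp_endorse)
    cn = co = ce = 0.0
    for n, o, e in zip(n_counts, obs_counts, expected_rate):
        cn += n
        co += o
        ce += n * e
        if cn > 0 and ce >= collapse_min and (cn - ce) >= collapse_min:
            groups.append((cn, co, ce))
            cn = co = ce = 0.0
    if cn > 0:
        if groups:
            n0, o0, e0 = groups.pop()
            groups.append((n0 + cn, o0 + co, e0 + ce))
        else:
            groups.append((cn, co, ce))
    n_groups = len(groups)
    dfree = n_groups - n_params
    if n_groups < 2 or dfree <= 0:
        return None, 0, n_groups
    stat = 0.0
    for n, o, e in groups:
        E = e / n
        O = o / n
        E = min(max(E, 1e-10), 1 - 1e-10)
        stat += n * (O - E) ** 2 / (E * (1 - E))
    return float(stat), dfree, n_groups


# ---------------------------------------------------------------------------
# Wald DIF
# ---------------------------------------------------------------------------


def wald_dif(
    X,
    Q: QMatrix,
    group: np.ndarray,
    item_id: str,
    options: FitOptions | None = None,
    init_probs=None,
) -> tuple[float, int, float]:
    """Wald test of group-specific parameters for one item.

    All other items anchor the groups on a common metric; the statistic is
    (d_R - d_F)' [Cov_R + Cov_F]^{-1} (d_R - d_F) on the delta scale with
    df = number of item parameters.  Symmetric in the group labels.
    """
    res = fit_em(
        X,
        Q,
        options=options,
        group=group,
        group_specific_items=(item_id,),
        init_probs=init_probs,
    )
    per = res.group_results[item_id]
    (ip_a, cov_a), (ip_b, cov_b) = per.values()
    d = ip_a.deltas - ip_b.deltas
    C = cov_a + cov_b
    try:
        stat = float(d @ np.linalg.solve(C, d))
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn(f"singular DIF covariance for item {item_id}; pseudo-inverse")
        stat = float(d @ np.linalg.pinv(C) @ d)
    dfree = d.shape[0]
    return stat, dfree, float(chi2.sf(stat, dfree))


def wald_dif_all(
    X,
    Q: QMatrix,
    group: np.ndarray,
    result: CalibrationResult | None = None,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Item-by-item Wald DIF over the whole instrument.

    When a pooled calibration is supplied its item probabilities warm-start
    each single-item refit, which typically converges in a few iterations.
    """
    init = [ip.probs for ip in result.item_params] if result is not None else None
    rows = []
    for item_id in Q.item_ids:
        stat, dfree, p = wald_dif(
            X, Q, group, item_id, options=options, init_probs=init
        )
        rows.append((item_id, stat, dfree, p))
    return pd.DataFrame(rows, columns=["item", "wald", "wald_df", "wald_p"])


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityReport:
    """Per-symptom classification consistency plus CTT split-half."""

    classification_consistency: pd.Series
    guttman_split_half: float


def classification_consistency(result: CalibrationResult) -> pd.Series:
    """Expected agreement of two classifications drawn from each posterior.

    For symptom k: mean over respondents of P_ik**2 + (1 - P_ik)**2; 1 at
    certain classification, 0.5 at a coin flip.
    """
    P = result.eap
    vals = (P**2 + (1 - P) ** 2).mean(axis=0)
    return pd.Series(vals, index=list(result.qmatrix.symptom_ids))


def guttman_split_half(X, split: str | tuple = "even-odd") -> float:
    """Guttman (Flanagan-Rulon) split-half: 2(1 - (V_A + V_B)/V_{A+B}).

    ``split`` is "even-odd" or an explicit (half_a_indices, half_b_indices)
    pair of column index sequences.  Complete cases only.
    """
    X = _check_responses(X)
    X = X[~np.isnan(X).any(axis=1)]
    J = X.shape[1]
    if split == "even-odd":
        a, b = np.arange(0, J, 2), np.arange(1, J, 2)
    else:
        a, b = (np.asarray(h, dtype=int) for h in split)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 items per half")
    sa, sb = X[:, a].sum(axis=1), X[:, b].sum(axis=1)
    vt = np.var(sa + sb, ddof=1)
    if vt == 0:
        raise ValueError("total score has zero variance; split-half undefined")
    return float(2.0 * (1.0 - (np.var(sa, ddof=1) + np.var(sb, ddof=1)) / vt))


# ---------------------------------------------------------------------------
# one-stop diagnostics table
# ---------------------------------------------------------------------------


def compute_item_diagnostics(
    result: CalibrationResult,
    X,
    group: np.ndarray | None = None,
    collapse_min: float = 1.0,
    options: FitOptions | None = None,
) -> pd.DataFrame:
    """Selection-ready table: item, disc, S-X² (stat/df/p), Wald DIF (stat/df/p).

    DIF columns are included only when a group covariate is given.
    """
    disc = pd.DataFrame(
        {
            "item": list(result.qmatrix.item_ids),
            "disc": [ip.discrimination for ip in result.item_params],
        }
    )
    fit = s_x2_item_fit(result, X, collapse_min=collapse_min)
    out = disc.merge(fit.drop(columns="sx2_groups"), on="item")
    if group is not None:
        dif = wald_dif_all(X, result.qmatrix, group, result=result, options=options)
        out = out.merge(dif, on="item")
    return out
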
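"""Respondent-level screening: symptom reports, PP-SPD, and validity metrics.

The screening statistic PP-SPD (posterior probability of schizotypal
personality disorder) is the probability that a respondent possesses at
least five of the nine DSM-V symptom criteria.  Two computations are
offered:

* ``pp_spd_marginal`` — the aggregation formula as commonly printed:
  treat the K symptom-possession probabilities P_ik as independent and sum
  the product-Bernoulli mass over all profiles with >= ``min_symptoms``
  ones.
* ``pp_spd_exact`` — sum the respondent's posterior mass over the latent
  classes with >= ``min_symptoms`` symptoms.  The two agree exactly when
  the posterior factorizes over symptoms and differ otherwise.

Symptom probabilities are dichotomized at a cut score (default 0.5, strict
``>``: a probability of exactly 0.5 is scored absent), and respondents with
PP-SPD strictly above 0.5 are flagged high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, pearsonr
from sklearn.metrics import roc_auc_score

from .gdina import CalibrationResult
from .profiles import MAX_K, enumerate_profiles

__all__ = [
    "pp_spd_marginal",
    "pp_spd_exact",
    "screen",
    "screening_metrics",
    "cohen_kappa",
    "symptom_correlations",
    "landis_koch_band",
    "ValidityMetrics",
    "AgreementStats",
    "plot_symptom_spectrum",
]


def pp_spd_marginal(symptom_probs: np.ndarray, min_symptoms: int = 5) -> float:
    """Probability of possessing >= min_symptoms symptoms from marginals.

    Exact enumeration of the 2**K lattice under independence of the
    symptom indicators given their marginal probabilities.
    """
    p = np.asarray(symptom_probs, dtype=float)
    if p.ndim != 1:
        raise ValueError("symptom_probs must be a 1-D vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("symptom probabilities must lie in [0, 1]")
    K = p.shape[0]
    if K > MAX_K:
        raise ValueError(f"K={K} exceeds exact-enumeration limit {MAX_K}")
    if not (0 <= min_symptoms <= K):
        raise ValueError("min_symptoms must be in [0, K]")
    A = enumerate_profiles(K)
    mask = A.sum(axis=1) >= min_symptoms
    terms = np.prod(np.where(A[mask] == 1, p, 1.0 - p), axis=1)
    return float(terms.sum())


def pp_spd_exact(posterior: np.ndarray, min_symptoms: int = 5) -> float | np.ndarray:
    """Posterior mass on latent classes with >= min_symptoms symptoms.

    ``posterior`` is a normalized vector over the 2**K lattice (or a matrix
    of such rows, returning one value per row).
    """
    post = np.asarray(posterior, dtype=float)
    one_row = post.ndim == 1
    post = np.atleast_2d(post)
    L = post.shape[1]
    K = int(np.log2(L))
    if 2**K != L:
        raise ValueError("posterior length must be a power of 2")
    if np.abs(post.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("posterior rows must sum to 1")
    mask = enumerate_profiles(K).sum(axis=1) >= min_symptoms
    vals = post[:, mask].sum(axis=1)
    return float(vals[0]) if one_row else vals


def screen(
    result: CalibrationResult,
    cut: float = 0.5,
    min_symptoms: int = 5,
    method: str = "marginal",
    respondent_ids=None,
) -> pd.DataFrame:
    """Per-respondent screening report.

    Columns: respondent id, the K symptom-possession probabilities, the K
    dichotomized symptom flags (prob > cut), PP-SPD by the chosen method
    ("marginal" or "exact"), and the high-risk flag (PP-SPD > 0.5).
    """
    P = result.eap
    N, K = P.shape
    ids = list(respondent_ids) if respondent_ids is not None else list(range(1, N + 1))
    if method == "marginal":
        pp = np.array([pp_spd_marginal(P[i], min_symptoms) for i in range(N)])
    elif method == "exact":
        pp = np.asarray(pp_spd_exact(result.posterior, min_symptoms))
    else:
        raise ValueError(f"unknown PP-SPD method {method!r}")
    sym = list(result.qmatrix.symptom_ids)
    out = pd.DataFrame({"respondent": ids})
    for k, s in enumerate(sym):
        out[f"p_{s}"] = P[:, k]
    for k, s in enumerate(sym):
        out[f"flag_{s}"] = (P[:, k] > cut).astype(int)
    out["pp_spd"] = pp
    out["high_risk"] = (pp > 0.5).astype(int)
    return out


@dataclass
class ValidityMetrics:
    """Screening accuracy against an external criterion."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    odds_ratio: float
    odds_ratio_ci: tuple[float, float]
    auc: float | None


def screening_metrics(flags, criterion, scores=None) -> ValidityMetrics:
    """Sensitivity, specificity, odds ratio (95% Wald CI) and AUC.

    ``flags`` is the screen's binary high-risk call, ``criterion`` the
    external high-risk label; ``scores`` (e.g. continuous PP-SPD) feeds the
    rank-based AUC with midrank tie handling.  The odds ratio uses the
    Haldane-Anscombe 0.5 correction when any cell is empty.
    """
    flags = np.asarray(flags, dtype=int)
    criterion = np.asarray(criterion, dtype=int)
    if flags.shape != criterion.shape:
        raise ValueError("flags and criterion must have equal length")
    if np.unique(criterion).size < 2:
        raise ValueError("criterion must contain both classes")
    tp = int(((flags == 1) & (criterion == 1)).sum())
    fp = int(((flags == 1) & (criterion == 0)).sum())
    fn = int(((flags == 0) & (criterion == 1)).sum())
    tn = int(((flags == 0) & (criterion == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    cells = np.array([tp, fp, fn, tn], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt((1 / cells).sum())
    ci = (float(np.exp(np.log(or_) - 1.96 * se)), float(np.exp(np.log(or_) + 1.96 * se)))
    auc = None
    if scores is not None:
        auc = float(roc_auc_score(criterion, np.asarray(scores, dtype=float)))
    return ValidityMetrics(tp, fp, fn, tn, float(sens), float(spec),
                           float(or_), ci, auc)


_LANDIS_KOCH = [
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


def landis_koch_band(kappa: float) -> str:
    """Qualitative agreement label; intervals are upper-inclusive, <0 is poor."""
    if kappa < 0:
        return "poor"
    for upper, label in _LANDIS_KOCH:
        if kappa <= upper + 1e-12:
            return label
    return "almost perfect"


@dataclass
class AgreementStats:
    kappa: float
    band: str
    p_value: float
    table: np.ndarray


def cohen_kappa(a, b) -> AgreementStats:
    """Cohen's kappa for two binary raters with a large-sample null z-test.

    kappa = (p_o - p_e) / (1 - p_e); the p-value tests kappa = 0 using the
    standard H0 variance from the marginal proportions.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    n = a.size
    table = np.array(
        [[(a == 1).astype(int) @ (b == 1).astype(int),
          (a == 1).astype(int) @ (b == 0).astype(int)],
         [(a == 0).astype(int) @ (b == 1).astype(int),
          (a == 0).astype(int) @ (b == 0).astype(int)]],
        dtype=float,
    )
    po = (table[0, 0] + table[1, 1]) / n
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        raise ValueError("degenerate marginals: expected agreement is 1")
    kappa = (po - pe) / (1 - pe)
    # H0 variance (Fleiss): depends only on the marginals
    s = sum(row[i] * col[i] * (row[i] + col[i]) for i in range(2))
    var0 = (pe + pe**2 - s) / (n * (1 - pe) ** 2)
    if var0 <= 0:
        p = 1.0
    else:
        z = kappa / np.sqrt(var0)
        p = float(2 * norm.sf(abs(z)))
    return AgreementStats(float(kappa), landis_koch_band(kappa), p, table)


def symptom_correlations(flags: np.ndarray, labels=None):
    """Pairwise phi correlations of dichotomized symptom indicators.

    Returns (corr, pvals) DataFrames; pairs involving a zero-variance column
    are NaN (flagged undefined).
    """
    F = np.asarray(flags, dtype=float)
    if F.ndim != 2 or F.shape[0] < 3:
        raise ValueError("need an N x K binary matrix with N >= 3")
    K = F.shape[1]
    labels = list(labels) if labels is not None else [f"C{k+1}" for k in range(K)]
    corr = np.full((K, K), np.nan)
    pval = np.full((K, K), np.nan)
    var = F.var(axis=0)
    for i in range(K):
        if var[i] == 0:
            continue
        corr[i, i] = 1.0
        pval[i, i] = 0.0
        for j in range(i + 1, K):
            if var[j] == 0:
                continue
            r, p = pearsonr(F[:, i], F[:, j])
            corr[i, j] = corr[j, i] = r
            pval[i, j] = pval[j, i] = p
    return (
        pd.DataFrame(corr, index=labels, columns=labels),
        pd.DataFrame(pval, index=labels, columns=labels),
    )


def plot_symptom_spectrum(report_row: pd.Series, symptom_ids, ax=None):
    """Bar chart of one respondent's symptom-possession probabilities.

    Optional visual analog of the individual score report; requires
    matplotlib (the ``plot`` extra).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    probs = [report_row[f"p_{s}"] for s in symptom_ids]
    ax.bar(list(symptom_ids), probs, color="steelblue")
    ax.axhline(0.5, color="grey", ls="--", lw=1)
    ax.set_ylim(0, 1)
    ax.set_ylabel("P(symptom present)")
    ax.set_title(f"respondent {report_row['respondent']}: "
                 f"PP-SPD = {report_row['pp_spd']:.2f}")
    return ax
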
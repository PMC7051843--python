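"""G-DINA model and marginal-maximum-likelihood EM calibration.

The G-DINA (generalized deterministic-input noisy-and-gate) item response
function with the identity link writes the endorsement probability of item j
for a respondent whose reduced profile is alpha* as

    P(X_j = 1 | alpha*) = delta_j0 + sum_k delta_jk alpha*_k
                        + sum_{k<k'} delta_jkk' alpha*_k alpha*_k'
                        + ... + delta_j12...K* prod_k alpha*_k,

i.e. an intercept (baseline endorsement probability with none of the item's
required symptoms), main effects for each required symptom, and interaction
terms up to the full order.  The model is saturated: the delta vector of
length 2**K*_j is a linear bijection of the vector of endorsement
probabilities over the item's 2**K*_j reduced profiles, so estimation is
carried out on the probability scale and mapped back to deltas.

Calibration maximizes the marginal likelihood

    L = prod_i sum_l nu_l prod_j P_jl^{x_ij} (1 - P_jl)^{1 - x_ij}

over the 2**K latent classes by EM: the E-step computes each respondent's
posterior over classes (log-space, so large J is safe) and expected counts
per item per reduced profile; the M-step sets each reduced-profile
probability to its expected endorsement rate (optionally projected onto the
monotone cone) and the class distribution nu to the average posterior.

Missing responses (NaN) are ignored item-wise in the likelihood, which is
valid under missing-at-random.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .profiles import QMatrix, enumerate_profiles, profile_to_index

__all__ = [
    "ItemParams",
    "CalibrationResult",
    "FitOptions",
    "design_matrix",
    "irf",
    "marginal_loglik",
    "e_step",
    "m_step",
    "fit_em",
    "eap_marginals",
    "map_profile",
]

logger = logging.getLogger(__name__)

#: probability clamp keeping endorsement probabilities off the boundary
EPS = 1e-4


def attr_subsets(kstar: int) -> list[tuple[int, ...]]:
    """Subsets of the item's required symptoms, ordered by (size, lexicographic).

    This is the delta ordering: intercept (empty set), main effects, two-way
    interactions, ..., the full interaction.
    """
    out: list[tuple[int, ...]] = []
    for size in range(kstar + 1):
        out.extend(itertools.combinations(range(kstar), size))
    return out


@lru_cache(maxsize=None)
def design_matrix(kstar: int) -> np.ndarray:
    """Saturated identity-link design matrix M with probs = M @ deltas.

    Rows are the 2**kstar reduced profiles in lattice order, columns the
    delta terms in :func:`attr_subsets` order; M[r, t] = 1 iff every symptom
    in term t is present in reduced profile r.  M is unit lower triangular up
    to column permutation, hence invertible.
    """
    lattice = enumerate_profiles(kstar) if kstar else np.zeros((1, 0), np.int8)
    subs = attr_subsets(kstar)
    M = np.ones((2**kstar, len(subs)))
    for t, s in enumerate(subs):
        if s:
            M[:, t] = lattice[:, list(s)].prod(axis=1)
    return M


@dataclass(frozen=True)
class ItemParams:
    """Per-item G-DINA coefficients.

    ``deltas`` has length 2**K*_j in (intercept, main effects, interactions,
    ..., full interaction) order.  ``probs`` is the induced endorsement
    probability per reduced profile (lattice order) — the two are linked by
    the saturated design matrix.
    """

    item_id: str
    deltas: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.deltas, dtype=float)
        n = d.shape[0]
        if n < 1 or (n & (n - 1)):
            raise ValueError(f"deltas length must be a power of 2, got {n}")
        object.__setattr__(self, "deltas", d)

    @property
    def n_attrs(self) -> int:
        return int(np.log2(self.deltas.shape[0]))

    @property
    def probs(self) -> np.ndarray:
        return design_matrix(self.n_attrs) @ self.deltas

    @classmethod
    def from_probs(cls, item_id: str, probs: np.ndarray) -> "ItemParams":
        probs = np.asarray(probs, dtype=float)
        n = probs.shape[0]
        kstar = int(np.log2(n))
        if 2**kstar != n:
            raise ValueError(f"probs length must be a power of 2, got {n}")
        deltas = np.linalg.solve(design_matrix(kstar), probs)
        return cls(item_id, deltas)

    @property
    def discrimination(self) -> float:
        """P(endorse | all required symptoms) - P(endorse | none)."""
        p = self.probs
        return float(p[-1] - p[0])


def irf(params: ItemParams, reduced: np.ndarray, eps: float = EPS) -> float:
    """Item response function: endorsement probability for a reduced profile.

    The identity-link sum of all delta terms whose symptoms are all present,
    clamped to [eps, 1 - eps].
    """
    reduced = np.asarray(reduced)
    if reduced.shape[0] != params.n_attrs:
        raise ValueError(
            f"reduced profile length {reduced.shape[0]} != item K*={params.n_attrs}"
        )
    r = profile_to_index(reduced) if reduced.size else 0
    return float(np.clip(params.probs[r], eps, 1 - eps))


# ---------------------------------------------------------------------------
# vectorized internals
# ---------------------------------------------------------------------------


def _check_responses(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("responses must be a 2-D respondents x items array")
    obs = ~np.isnan(X)
    if not np.isin(X[obs], (0.0, 1.0)).all():
        raise ValueError("responses must be 0, 1 or missing (NaN)")
    return X

def _reduced_index(Q: QMatrix) -> list[np.ndarray]:
    """Per item: map from class index (lattice order) to reduced-profile index."""
    A = enumerate_profiles(Q.n_symptoms)
    out = []
    for j in range(Q.n_items):
        idx = Q.item_attrs(j)
        if idx.size == 0:
            raise ValueError(f"item {Q.item_ids[j]}: Q-matrix row is all zeros")
        weights = 1 << (idx.size - 1 - np.arange(idx.size))
        out.append((A[:, idx] @ weights).astype(np.intp))
    return out


def _class_prob_matrix(probs: list[np.ndarray], rindex: list[np.ndarray]) -> np.ndarray:
    """(J, 2**K) endorsement probability of each item under each class."""
    return np.stack([p[r] for p, r in zip(probs, rindex)])


def _posterior(X, Pmat, log_nu):
    """Log-space E-step core: posterior (N, L) and total marginal loglik."""
    obs = ~np.isnan(X)
    X1 = np.where(obs, X, 0.0)
    X0 = np.where(obs, 1.0 - X, 0.0)
    with np.errstate(divide="ignore"):
        logP = np.log(Pmat)
        log1P = np.log1p(-Pmat)
    ll = X1 @ logP + X0 @ log1P + log_nu[None, :]  # (N, L)
    norm = logsumexp(ll, axis=1)
    post = np.exp(ll - norm[:, None])
    return post, float(norm.sum())


def _expected_counts(X, post, rindex, nred):
    """Per item: (N_bar, R_bar) over reduced profiles, from posteriors."""
    obs = ~np.isnan(X)
    X1 = np.where(obs, X, 0.0)
    CN = post.T @ obs.astype(float)  # (L, J) expected exposure per class
    CR = post.T @ X1  # (L, J) expected endorsements per class
    out = []
    for j, (r, n) in enumerate(zip(rindex, nred)):
        Nbar = np.bincount(r, weights=CN[:, j], minlength=n)
        Rbar = np.bincount(r, weights=CR[:, j], minlength=n)
        out.append((Nbar, Rbar))
    return out


def _isotone_project(p: np.ndarray, w: np.ndarray, max_pass: int = 200) -> np.ndarray:
    """Weighted projection of reduced-profile probabilities onto the monotone cone.

    Monotone means non-decreasing along the subset partial order (adding a
    required symptom never lowers the endorsement probability).  For K*=1
    this is exact weighted pooling; for K*>1 violated covering pairs are
    pooled iteratively until none remain.
    """
    p = p.copy()
    n = p.shape[0]
    if n <= 1:
        return p
    kstar = int(np.log2(n))
    pairs = [
        (r, r | (1 << b))
        for r in range(n)
        for b in range(kstar)
        if not r & (1 << b)
    ]
    w = np.maximum(w, 1e-12)
    for _ in range(max_pass):
        changed = False
        for lo, hi in pairs:
            if p[lo] > p[hi] + 1e-12:
                avg = (w[lo] * p[lo] + w[hi] * p[hi]) / (w[lo] + w[hi])
                p[lo] = p[hi] = avg
                changed = True
        if not changed:
            break
    return p


# ---------------------------------------------------------------------------
# public operations (spec-level wrappers around the internals)
# ---------------------------------------------------------------------------


def marginal_loglik(
    X, item_params: list[ItemParams], Q: QMatrix, nu: np.ndarray
) -> float:
    """Marginal log-likelihood of binary responses under a G-DINA model."""
    X = _check_responses(X)
    nu = np.asarray(nu, dtype=float)
    rindex = _reduced_index(Q)
    probs = [np.clip(ip.probs, EPS, 1 - EPS) for ip in item_params]
    Pmat = _class_prob_matrix(probs, rindex)
    with np.errstate(divide="ignore"):
        log_nu = np.log(nu)
    _, ll = _posterior(X, Pmat, log_nu)
    return ll


def e_step(X, item_params: list[ItemParams], Q: QMatrix, nu: np.ndarray):
    """Posterior class probabilities and expected counts.

    Returns ``(posterior, counts, loglik)`` where ``counts[j]`` is the pair
    (N_bar, R_bar) of expected exposures and endorsements of item j per
    reduced profile.
    """
    X = _check_responses(X)
    nu = np.asarray(nu, dtype=float)
    rindex = _reduced_index(Q)
    nred = [2 ** Q.item_attrs(j).size for j in range(Q.n_items)]
    probs = [np.clip(ip.probs, EPS, 1 - EPS) for ip in item_params]
    Pmat = _class_prob_matrix(probs, rindex)
    with np.errstate(divide="ignore"):
        log_nu = np.log(nu)
    post, ll = _posterior(X, Pmat, log_nu)
    counts = _expected_counts(X, post, rindex, nred)
    return post, counts, ll


def m_step(
    counts,
    item_params: list[ItemParams],
    posterior: np.ndarray,
    monotone: bool = True,
    eps: float = EPS,
):
    """Closed-form identity-link M-step.

    Each reduced-profile probability becomes its expected endorsement rate
    R_bar/N_bar (carried forward with a warning when a cell has no expected
    exposure), optionally projected onto the monotone cone; the class
    distribution becomes the average posterior.
    """
    new_params = []
    for ip, (Nbar, Rbar) in zip(item_params, counts):
        old = np.clip(ip.probs, eps, 1 - eps)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(Nbar > 1e-10, Rbar / np.maximum(Nbar, 1e-300), old)
        if (Nbar <= 1e-10).any():
            logger.warning(
                "item %s: empty reduced-profile cell, carrying forward", ip.item_id
            )
        p = np.clip(p, eps, 1 - eps)
        if monotone:
            p = _isotone_project(p, Nbar)
        new_params.append(ItemParams.from_probs(ip.item_id, p))
    nu = posterior.mean(axis=0)
    nu = nu / nu.sum()
    return new_params, nu


@dataclass
class FitOptions:
    """EM controls.

    ``tol`` is on the max absolute change of any reduced-profile probability,
    ``loglik_tol`` on the relative log-likelihood change; both must be met.
    ``monotone`` projects item probabilities onto the monotone cone each
    M-step so the discrimination index stays non-negative.  ``struct``
    chooses the structural model for the class distribution: "saturated"
    (one free probability per latent class) or "independent" (product of
    per-symptom prevalences, for small samples).
    """

    max_iter: int = 1000
    tol: float = 1e-4
    loglik_tol: float = 1e-6
    monotone: bool = True
    eps: float = EPS
    struct: str = "saturated"


@dataclass
class CalibrationResult:
    """Everything the downstream diagnostics and screening stages need."""

    item_params: list[ItemParams]
    class_dist: np.ndarray
    posterior: np.ndarray
    eap: np.ndarray
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    covariance: list[np.ndarray]
    qmatrix: QMatrix
    options: FitOptions
    # present only for group-specific (DIF) fits: per studied item,
    # {group_label: (ItemParams, delta-covariance)}
    group_results: dict | None = None


def _initial_probs(Q: QMatrix) -> list[np.ndarray]:
    """Deterministic start: baseline 0.2, full-mastery 0.8, linear between."""
    out = []
    for j in range(Q.n_items):
        kstar = Q.item_attrs(j).size
        lattice = enumerate_profiles(kstar)
        frac = lattice.sum(axis=1) / kstar
        out.append(0.2 + 0.6 * frac)
    return out


def _independent_nu(nu: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Project nu onto the independent-attributes structural model."""
    pk = np.clip(nu @ A, 1e-6, 1 - 1e-6)
    log_nu = A @ np.log(pk) + (1 - A) @ np.log1p(-pk)
    nu = np.exp(log_nu)
    return nu / nu.sum()


def _opg_covariance(X, post, probs, rindex, rows=None):
    """Outer-product-of-gradients covariance of each item's delta vector.

    The score of respondent i w.r.t. a reduced-profile probability is the
    posterior mass on the matching classes times (x - p)/(p(1-p)); the
    empirical information is the sum of score outer products, inverted
    (pseudo-inverse on singular blocks) and mapped to the delta scale through
    the saturated design matrix.
    """
    if rows is None:
        rows = np.arange(X.shape[0])
    covs = []
    for j, (p, r) in enumerate(zip(probs, rindex)):
        n = p.shape[0]
        kstar = int(np.log2(n))
        obs = rows[~np.isnan(X[rows, j])]
        # posterior mass per reduced profile: (n_i, n)
        mass = np.zeros((obs.size, n))
        for rr in range(n):
            mass[:, rr] = post[obs][:, r == rr].sum(axis=1)
        x = X[obs, j][:, None]
        G = mass * (x - p[None, :]) / (p * (1 - p))[None, :]
        info = G.T @ G
        try:
            cov_p = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular information for item {j}; using pseudo-inverse")
            cov_p = np.linalg.pinv(info)
        Minv = np.linalg.inv(design_matrix(kstar))
        covs.append(Minv @ cov_p @ Minv.T)
    return covs


def fit_em(
    X,
    Q: QMatrix,
    options: FitOptions | None = None,
    group: np.ndarray | None = None,
    group_specific_items: tuple[str, ...] = (),
    init_probs: list[np.ndarray] | None = None,
    compute_covariance: bool = True,
) -> CalibrationResult:
    """Calibrate a G-DINA model by marginal-maximum-likelihood EM.

    Parameters
    ----------
    X : (N, J) array of 0/1 responses, NaN for missing.
    Q : the Q-matrix; columns define the K-symptom latent lattice.
    group : optional binary covariate; items named in
        ``group_specific_items`` get separate parameters per group (used by
        the Wald DIF test), all other items anchor the two groups.
    init_probs : optional warm start, per-item reduced-profile probabilities
        (shared across groups).

    Initialization is deterministic (baseline 0.2, full-mastery 0.8, uniform
    class distribution), so repeated runs are identical.
    """
    opts = options or FitOptions()
    X = _check_responses(X)
    N, J = X.shape
    if N < 2:
        raise ValueError("need at least 2 respondents")
    if J != Q.n_items:
        raise ValueError(f"responses have {J} items but Q-matrix has {Q.n_items}")
    if J < 2:
        raise ValueError("need at least 2 items to calibrate")
    if np.isnan(X).all(axis=1).any():
        raise ValueError("a respondent has no observed responses")

    K = Q.n_symptoms
    A = enumerate_profiles(K).astype(float)
    L = 2**K
    rindex = _reduced_index(Q)
    nred = [2 ** Q.item_attrs(j).size for j in range(J)]

    if group is not None:
        group = np.asarray(group)
        labels = np.unique(group)
        if labels.size != 2:
            raise ValueError("group must have exactly two levels")
        group_rows = [np.flatnonzero(group == g) for g in labels]
        if any(r.size == 0 for r in group_rows):
            raise ValueError("both groups must be non-empty")
    else:
        labels = np.array([0])
        group_rows = [np.arange(N)]
    n_groups = len(group_rows)
    gs_items = {Q.item_ids.index(i) for i in group_specific_items}
    if gs_items and group is None:
        raise ValueError("group_specific_items requires a group vector")

    base = init_probs if init_probs is not None else _initial_probs(Q)
    # probs[g][j]; anchor items share values across groups
    probs = [[np.clip(np.asarray(p, float).copy(), opts.eps, 1 - opts.eps) for p in base]
             for _ in range(n_groups)]
    nu = np.full(L, 1.0 / L)

    loglik_path = []
    prev_ll = -np.inf
    post = np.zeros((N, L))
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        # E-step per group
        ll_total = 0.0
        with np.errstate(divide="ignore"):
            log_nu = np.log(nu)
        counts_g = []
        for g, rows in enumerate(group_rows):
            Pmat = _class_prob_matrix(probs[g], rindex)
            pg, llg = _posterior(X[rows], Pmat, log_nu)
            post[rows] = pg
            ll_total += llg
            counts_g.append(_expected_counts(X[rows], pg, rindex, nred))
        loglik_path.append(ll_total)

        # M-step
        delta_max = 0.0
        for j in range(J):
            if j in gs_items:
                per_group = [(g, counts_g[g][j]) for g in range(n_groups)]
            else:
                Nbar = sum(counts_g[g][j][0] for g in range(n_groups))
                Rbar = sum(counts_g[g][j][1] for g in range(n_groups))
                per_group = [(None, (Nbar, Rbar))]
            for g, (Nbar, Rbar) in per_group:
                old = probs[0][j] if g is None else probs[g][j]
                with np.errstate(invalid="ignore"):
                    p = np.where(Nbar > 1e-10, Rbar / np.maximum(Nbar, 1e-300), old)
                p = np.clip(p, opts.eps, 1 - opts.eps)
                if opts.monotone:
                    p = _isotone_project(p, Nbar)
                delta_max = max(delta_max, float(np.abs(p - old).max()))
                if g is None:
                    for gg in range(n_groups):
                        probs[gg][j] = p
                else:
                    probs[g][j] = p
        nu = post.mean(axis=0)
        nu = nu / nu.sum()
        if opts.struct == "independent":
            nu = _independent_nu(nu, A)

        rel = abs(ll_total - prev_ll) / max(abs(ll_total), 1.0)
        if delta_max < opts.tol and rel < opts.loglik_tol:
            converged = True
            break
        prev_ll = ll_total

    # final E-step so posterior/loglik match the returned parameters
    with np.errstate(divide="ignore"):
        log_nu = np.log(nu)
    ll_total = 0.0
    for g, rows in enumerate(group_rows):
        Pmat = _class_prob_matrix(probs[g], rindex)
        pg, llg = _posterior(X[rows], Pmat, log_nu)
        post[rows] = pg
        ll_total += llg
    loglik_path.append(ll_total)

    if not converged:
        warnings.warn(f"EM did not converge in {opts.max_iter} iterations")

    item_params = [
        ItemParams.from_probs(Q.item_ids[j], probs[0][j]) for j in range(J)
    ]
    covariance = (
        _opg_covariance(X, post, probs[0], rindex) if compute_covariance else []
    )

    group_results = None
    if gs_items:
        group_results = {}
        for j in sorted(gs_items):
            per = {}
            for g, rows in enumerate(group_rows):
                ip = ItemParams.from_probs(Q.item_ids[j], probs[g][j])
                cov = _opg_covariance(
                    X, post, [probs[g][j]], [rindex[j]], rows=rows
                )[0] if compute_covariance else None
                per[labels[g]] = (ip, cov)
            group_results[Q.item_ids[j]] = per

    eap = post @ A
    return CalibrationResult(
        item_params=item_params,
        class_dist=nu,
        posterior=post,
        eap=eap,
        loglik=ll_total,
        loglik_path=np.asarray(loglik_path),
        n_iter=it,
        converged=converged,
        covariance=covariance,
        qmatrix=Q,
        options=opts,
        group_results=group_results,
    )


def eap_marginals(result: CalibrationResult) -> np.ndarray:
    """Per-respondent symptom possession probabilities P_ik.

    P_ik is the posterior mass on the classes with alpha_k = 1 — the
    expected-a-posteriori marginal for symptom k.
    """
    A = enumerate_profiles(result.qmatrix.n_symptoms).astype(float)
    return result.posterior @ A


def map_profile(result: CalibrationResult) -> np.ndarray:
    """Maximum-a-posteriori profile per respondent (ties: lowest lattice index)."""
    A = enumerate_profiles(result.qmatrix.n_symptoms)
    return A[np.argmax(result.posterior, axis=1)]
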
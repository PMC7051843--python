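"""Synthetic SPQ-like datasets with the structure the pipeline assumes.

No respondent-level data accompany the screening study this package
emulates, so every stage is exercised on simulated data built to match the
published summary structure:

* **Population**: nine correlated binary symptoms.  True profiles come from
  a thresholded multivariate normal (probit copula): a latent normal vector
  with a given correlation matrix is dichotomized at the quantile matching
  each symptom's prevalence.  Default prevalences sit in the 0.27-0.48
  range and the default latent correlation echoes the published
  symptom-classification correlations (0.04-0.68).
* **Instrument**: 74 single-attribute items balanced over the nine
  criteria (8 items each, 9 for the last two), baseline endorsement
  probabilities delta_j0 in [0.05, 0.30] and discriminations in
  [0.30, 0.60], matching the reported 0.302-0.569 discrimination regime.
  Items listed in ``dif_items`` get parameters shifted for the focal group
  (baseline up, main effect down, so full-mastery endorsement is
  unchanged).
* **External criterion**: each true symptom indicator flipped independently
  with a small error probability, then the >= 6-symptom high-risk rule
  applied — emulating a PDQ-4-style validation measure with the cutoff
  reported for comparable samples.

One master seed is expanded into independent per-stage substreams
(profiles, instrument, responses, group, criterion), so regenerating one
stage never perturbs another and datasets are reproducible bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gdina import ItemParams
from .profiles import QMatrix, default_symptom_ids

__all__ = [
    "PopulationSpec",
    "InstrumentSpec",
    "SyntheticDataset",
    "DEFAULT_PREVALENCES",
    "DEFAULT_LATENT_CORRELATION",
    "default_qmatrix",
    "gen_profiles",
    "gen_instrument",
    "gen_responses",
    "gen_criterion",
    "simulate_dataset",
]

#: default per-symptom prevalences (nine-criterion regime, range 0.27-0.48)
DEFAULT_PREVALENCES = np.array(
    [0.32, 0.43, 0.41, 0.31, 0.27, 0.34, 0.36, 0.48, 0.31]
)


def _default_corr() -> np.ndarray:
    C = np.eye(9)
    lower = {
        (1, 0): .391, (2, 0): .436, (2, 1): .147, (3, 0): .573, (3, 1): .368,
        (3, 2): .525, (4, 0): .506, (4, 1): .237, (4, 2): .363, (4, 3): .618,
        (5, 0): .250, (5, 1): .474, (5, 2): .172, (5, 3): .501, (5, 4): .584,
        (6, 0): .429, (6, 1): .414, (6, 2): .105, (6, 3): .441, (6, 4): .509,
        (6, 5): .498, (7, 0): .235, (7, 1): .585, (7, 2): .043, (7, 3): .393,
        (7, 4): .339, (7, 5): .679, (7, 6): .588, (8, 0): .559, (8, 1): .294,
        (8, 2): .415, (8, 3): .659, (8, 4): .621, (8, 5): .546, (8, 6): .462,
        (8, 7): .428,
    }
    for (i, j), v in lower.items():
        C[i, j] = C[j, i] = v
    return C


#: default latent (tetrachoric-scale) symptom correlation matrix
DEFAULT_LATENT_CORRELATION = _default_corr()


def default_qmatrix(J: int = 74, K: int = 9) -> QMatrix:
    """Balanced single-attribute Q-matrix: J items spread over K symptoms.

    The default 74/9 split assigns (8,8,8,8,8,8,8,9,9) items per symptom
    (mean 8.2); a 47-item instrument splits (5,5,5,5,5,5,5,6,6) (mean 5.2).
    Items are interleaved across symptoms, mirroring questionnaire layouts
    that cycle through criteria.
    """
    if J < K:
        raise ValueError("need at least one item per symptom")
    q = np.zeros((J, K), dtype=np.int8)
    for j in range(J):
        q[j, j % K] = 1
    return QMatrix(q, tuple(str(j + 1) for j in range(J)),
                   tuple(default_symptom_ids(K)))


@dataclass(frozen=True)
class PopulationSpec:
    """Latent population: correlated binary symptoms via a probit copula."""

    N: int = 980
    K: int = 9
    prevalences: np.ndarray | None = None
    latent_correlation: np.ndarray | None = None

    def __post_init__(self):
        # defaults follow the nine-criterion regime; for K < 9 the leading
        # block is used so scaled-down simulations keep the same structure
        if self.prevalences is None:
            if self.K > 9:
                raise ValueError("prevalences required when K > 9")
            object.__setattr__(self, "prevalences",
                               DEFAULT_PREVALENCES[: self.K].copy())
        if self.latent_correlation is None:
            if self.K > 9:
                raise ValueError("latent_correlation required when K > 9")
            object.__setattr__(
                self, "latent_correlation",
                DEFAULT_LATENT_CORRELATION[: self.K, : self.K].copy())
        p = np.asarray(self.prevalences, dtype=float)
        C = np.asarray(self.latent_correlation, dtype=float)
        if p.shape != (self.K,):
            raise ValueError("prevalences must have length K")
        if ((p <= 0) | (p >= 1)).any():
            raise ValueError("prevalences must lie in (0, 1)")
        if C.shape != (self.K, self.K):
            raise ValueError("latent_correlation must be K x K")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("latent_correlation must be symmetric with unit diagonal")
        object.__setattr__(self, "prevalences", p)
        object.__setattr__(self, "latent_correlation", C)


@dataclass(frozen=True)
class InstrumentSpec:
    """Item bank: single-attribute items with configurable difficulty regime."""

    Q: QMatrix = field(default_factory=default_qmatrix)
    baseline_range: tuple[float, float] = (0.05, 0.30)
    disc_range: tuple[float, float] = (0.30, 0.60)
    dif_items: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        b0, b1 = self.baseline_range
        d0, d1 = self.disc_range
        if not (0 <= b0 <= b1 < 1) or not (0 < d0 <= d1 < 1):
            raise ValueError("invalid baseline or discrimination range")
        if b1 + d1 > 1:
            raise ValueError(
                f"infeasible ranges: max baseline {b1} + max disc {d1} > 1"
            )
        for item, shift in self.dif_items.items():
            if item not in self.Q.item_ids:
                raise ValueError(f"unknown DIF item {item}")
            if abs(shift) >= 1:
                raise ValueError("dif_shift must be in (-1, 1)")


@dataclass
class SyntheticDataset:
    responses: np.ndarray        # N x J in {0, 1}
    true_profiles: np.ndarray    # N x K in {0, 1}
    true_params: list[ItemParams]
    focal_params: dict[str, ItemParams]  # group-1 parameters of DIF items
    group: np.ndarray            # N in {0, 1}
    criterion_flags: np.ndarray  # N x K
    criterion_highrisk: np.ndarray  # N
    qmatrix: QMatrix
    seed: int


def _repair_correlation(C: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(C)
    if vals.min() > 1e-10:
        return C
    warnings.warn("latent correlation not positive definite; clipping eigenvalues")
    vals = np.clip(vals, 1e-6, None)
    C = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


#: substream layout: 0 profiles, 1 instrument, 2 responses, 3 criterion,
#: 4 group membership, 5 missingness mask
def _substream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(6)[stage])


def gen_profiles(spec: PopulationSpec, seed: int) -> np.ndarray:
    """Draw true symptom profiles from the thresholded multivariate normal."""
    rng = _substream(seed, 0)
    from scipy.stats import norm

    C = _repair_correlation(spec.latent_correlation)
    Z = rng.multivariate_normal(np.zeros(spec.K), C, size=spec.N,
                                method="cholesky")
    thresh = norm.ppf(1 - spec.prevalences)
    return (Z > thresh[None, :]).astype(np.int8)


def gen_instrument(
    spec: InstrumentSpec, seed: int
) -> tuple[list[ItemParams], dict[str, ItemParams]]:
    """Draw single-attribute item parameters, monotone by construction.

    Returns reference-group parameters for all items and the focal-group
    parameters of DIF items (baseline shifted up by ``dif_shift``, main
    effect down by the same amount, clipped to keep probabilities valid).
    """
    rng = _substream(seed, 1)
    Q = spec.Q
    params = []
    focal = {}
    for j, item_id in enumerate(Q.item_ids):
        kstar = Q.item_attrs(j).size
        if kstar != 1:
            raise NotImplementedError("generator draws single-attribute items only")
        b = rng.uniform(*spec.baseline_range)
        d = rng.uniform(*spec.disc_range)
        params.append(ItemParams(item_id, np.array([b, d])))
        if item_id in spec.dif_items:
            shift = spec.dif_items[item_id]
            b_f = float(np.clip(b + shift, 0.01, 0.99))
            d_f = float(np.clip(d - (b_f - b), 0.01, 0.99 - b_f))
            focal[item_id] = ItemParams(item_id, np.array([b_f, d_f]))
    return params, focal


def gen_responses(
    true_profiles: np.ndarray,
    params: list[ItemParams],
    Q: QMatrix,
    seed: int,
    group: np.ndarray | None = None,
    focal_params: dict[str, ItemParams] | None = None,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Bernoulli responses from the G-DINA response function.

    Respondents in group 1 answer DIF items under the focal parameters.
    ``missing_rate`` applies an optional MCAR mask (NaN).
    """
    alpha = np.asarray(true_profiles)
    N = alpha.shape[0]
    rng = _substream(seed, 2)
    focal_params = focal_params or {}
    if group is None:
        group = np.zeros(N, dtype=int)
    X = np.empty((N, Q.n_items), dtype=float)
    for j, item_id in enumerate(Q.item_ids):
        q_row = Q.q[j]
        ref = params[j]
        foc = focal_params.get(item_id, ref)
        red = alpha[:, q_row.astype(bool)]
        # vectorized irf lookup via the reduced-profile index
        weights = 1 << (red.shape[1] - 1 - np.arange(red.shape[1]))
        ridx = red @ weights
        pr = np.clip(ref.probs, 0.0, 1.0)[ridx]
        pf = np.clip(foc.probs, 0.0, 1.0)[ridx]
        p = np.where(group == 1, pf, pr)
        X[:, j] = (rng.random(N) < p).astype(float)
    if missing_rate > 0:
        mask = _substream(seed, 5).random(X.shape) < missing_rate
        X[mask] = np.nan
    return X


def gen_criterion(
    true_profiles: np.ndarray,
    flip_prob: float = 0.1,
    highrisk_min: int = 6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy external criterion: flip each symptom flag, apply the >=6 rule."""
    if not (0 <= flip_prob < 0.5):
        raise ValueError("flip_prob must be in [0, 0.5)")
    alpha = np.asarray(true_profiles)
    rng = _substream(seed, 3)
    flips = rng.random(alpha.shape) < flip_prob
    flags = np.where(flips, 1 - alpha, alpha).astype(np.int8)
    highrisk = (flags.sum(axis=1) >= highrisk_min).astype(np.int8)
    return flags, highrisk


def simulate_dataset(
    pop: PopulationSpec | None = None,
    inst: InstrumentSpec | None = None,
    seed: int = 0,
    flip_prob: float = 0.1,
    highrisk_min: int = 6,
    group_fraction: float = 0.5,
    missing_rate: float = 0.0,
) -> SyntheticDataset:
    """One call for the whole study design; reproducible from the seed alone."""
    pop = pop or PopulationSpec()
    inst = inst or InstrumentSpec()
    if pop.K != inst.Q.n_symptoms:
        raise ValueError("population K and Q-matrix symptom count differ")
    alpha = gen_profiles(pop, seed)
    params, focal = gen_instrument(inst, seed)
    # group membership from its own substream so it is independent of symptoms
    rng_g = _substream(seed, 4)
    group = (rng_g.random(pop.N) < group_fraction).astype(int)
    X = gen_responses(alpha, params, inst.Q, seed, group=group,
                      focal_params=focal, missing_rate=missing_rate)
    flags, highrisk = gen_criterion(alpha, flip_prob, highrisk_min, seed)
    return SyntheticDataset(
        responses=X,
        true_profiles=alpha,
        true_params=params,
        focal_params=focal,
        group=group,
        criterion_flags=flags,
        criterion_highrisk=highrisk,
        qmatrix=inst.Q,
        seed=seed,
    )
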
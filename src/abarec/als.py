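"""Implicit-feedback collaborative filtering by alternating least squares.

Patients and treatment codes form a patient x item interaction matrix R with
nonnegative ratings r_ui: r_ui > 0 exactly where code i sits in patient u's
clinician plan, with magnitude the patient's SRS-2 total T-score rescaled to
[1, 10]. From R derive the binary preference p_ui = 1[r_ui > 0] and the
confidence

    c_ui = 1 + alpha * r_ui,

and factorise by minimising the confidence-weighted L2 cost

    C = sum_{u,i} c_ui (p_ui - x_u^T y_i)^2
        + lambda (sum_u ||x_u||^2 + sum_i ||y_i||^2),

summed over *all* cells: unobserved cells carry p = 0 at confidence 1, which
is what makes the absence of an interaction weakly informative. (A strict
observed-cells-only mode exists for comparison but is not the default.)

Each ALS half-sweep solves the exact per-row ridge normal equations

    x_u <- (Y^T C_u Y + lambda I)^{-1} Y^T C_u p_u

(and symmetrically for items), so the cost is non-increasing across sweeps.
Predicted affinity is r_hat_ui = x_u^T y_i; the top-N unobserved candidates
ranked by r_hat form the recommendation.

Model/Results interface::

    M = build_interactions(cohort, level="target")
    split = mask_split(M, fraction=0.2, seed=1)
    res = ImplicitALS(split.train, ConfidenceParams(seed=1)).fit()
    res.recommend("P007", n=5)
    res.summary()
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .cohort import Cohort, TreatmentCode
from .exceptions import (
    ConfigError,
    EmptyInteractionError,
    MissingFeatureError,
    NumericError,
)

__all__ = [
    "InteractionMatrix",
    "ConfidenceParams",
    "MaskSplit",
    "RankedItem",
    "build_interactions",
    "sparsity_ratio",
    "confidence",
    "mask_split",
    "implicit_cost",
    "als_fit",
    "ImplicitALS",
    "ImplicitALSResults",
    "grid_search_alpha",
]

logger = logging.getLogger(__name__)

#: Default rating range the SRS-2 total T-score is rescaled to.
RATING_RANGE = (1.0, 10.0)

#: T-score range used for the linear rescale (T-scores live in [30, 100]).
T_RANGE = (30.0, 100.0)


@dataclass(frozen=True)
class InteractionMatrix:
    """Patients x items ratings; preferences are derived, not stored."""

    patient_ids: tuple[str, ...]
    item_ids: tuple[TreatmentCode, ...]
    ratings: np.ndarray  # dense nonnegative (n_patients, n_items)
    level: str

    @property
    def preferences(self) -> np.ndarray:
        return (self.ratings > 0).astype(float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ratings.shape

    def to_sparse(self) -> sparse.csr_matrix:
        return sparse.csr_matrix(self.ratings)


@dataclass(frozen=True)
class ConfidenceParams:
    """ALS hyperparameters.

    alpha scales rating into confidence (c = 1 + alpha r); it is not given a
    value in the source study ("must be tuned"), so the default 40 follows the
    implicit-feedback ALS literature. n_factors / n_iterations default to the
    target-level settings (20 factors, 200 sweeps); the domain-level model
    uses 22 factors and 150 sweeps. tol is a relative-cost-change safety
    valve on top of the fixed sweep budget.
    """

    alpha: float = 40.0
    regularization: float = 0.10
    n_factors: int = 20
    n_iterations: int = 200
    seed: int = 0
    tol: float = 1e-4
    all_cells: bool = True  # False: cost restricted to observed cells

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ConfigError("alpha must be positive (it is a tuned model parameter)")
        if self.regularization < 0:
            raise ConfigError("regularization must be nonnegative")
        if self.n_factors < 1:
            raise ConfigError("n_factors must be positive")
        if self.n_iterations < 0:
            raise ConfigError("n_iterations must be nonnegative")
        if self.tol < 0:
            raise ConfigError("tol must be nonnegative")


DOMAIN_PARAMS = ConfidenceParams(n_factors=22, n_iterations=150)
TARGET_PARAMS = ConfidenceParams(n_factors=20, n_iterations=200)


@dataclass(frozen=True)
class MaskSplit:
    """Training matrix with a per-user stratified 20% of positives held out."""

    train: InteractionMatrix
    held_out: frozenset[tuple[int, int]]  # (row, col) indices, nonzero in the source
    fraction: float
    seed: int


def build_interactions(
    cohort: Cohort,
    level: str = "target",
    rating_range: tuple[float, float] = RATING_RANGE,
) -> InteractionMatrix:
    """Patient x code ratings from plans and SRS-2 totals.

    r_ui > 0 exactly for codes in participant u's plan; the magnitude is u's
    SRS-2 total T-score linearly rescaled from [30, 100] to ``rating_range``.
    Items are every code observed at ``level`` in any plan, in ascending code
    order. Participants without a plan keep an all-zero row (logged).
    """
    if rating_range[0] >= rating_range[1] or rating_range[0] < 0:
        raise ConfigError(f"rating_range must be increasing and nonnegative: {rating_range}")
    if len(cohort) == 0:
        raise EmptyInteractionError("cohort has no participants")
    items = sorted({c for plan in cohort.plans for c in plan.codes(level)})
    if not items:
        raise EmptyInteractionError(f"no {level}-level codes in any plan")
    col = {c: j for j, c in enumerate(items)}
    pids = tuple(cohort.participant_ids())
    ratings = np.zeros((len(pids), len(items)))
    rlo, rhi = rating_range
    tlo, thi = T_RANGE
    for i, pid in enumerate(pids):
        plan = cohort.plan_for(pid)
        if plan is None or not plan.codes(level):
            logger.warning("participant %s has no %s-level plan; all-zero row", pid, level)
            continue
        prof = cohort.profile_for(pid, 0)
        t = prof.srs2_total_t if prof is not None else (tlo + thi) / 2
        rating = rlo + (rhi - rlo) * (np.clip(t, tlo, thi) - tlo) / (thi - tlo)
        for code in plan.codes(level):
            ratings[i, col[code]] = rating
    return InteractionMatrix(pids, tuple(items), ratings, level)


def sparsity_ratio(M: InteractionMatrix) -> float:
    """Fraction of cells that are zero (0 dense .. 1 empty)."""
    n = M.ratings.size
    if n == 0:
        raise EmptyInteractionError("zero-size interaction matrix")
    return float((M.ratings == 0).sum() / n)


def confidence(r_ui: float, alpha: float) -> float:
    """Confidence attached to one rating: c = 1 + alpha * r."""
    if r_ui < 0:
        raise ConfigError(f"rating must be nonnegative, got {r_ui}")
    if alpha <= 0:
        raise ConfigError(f"alpha must be positive, got {alpha}")
    return 1.0 + alpha * r_ui


def mask_split(M: InteractionMatrix, fraction: float = 0.2, seed: int = 0) -> MaskSplit:
    """Hold out ~``fraction`` of each user's positive cells for blind validation.

    Stratified per user so nobody is entirely unseen: a user with a single
    interaction keeps it. Deterministic per seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigError(f"mask fraction must lie strictly in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    held: set[tuple[int, int]] = set()
    train = M.ratings.copy()
    for u in range(M.shape[0]):
        cols = np.flatnonzero(M.ratings[u])
        n_mask = min(int(round(fraction * len(cols))), len(cols) - 1) if len(cols) else 0
        if n_mask <= 0:
            continue
        for j in rng.choice(cols, size=n_mask, replace=False):
            held.add((u, int(j)))
            train[u, int(j)] = 0.0
    masked = InteractionMatrix(M.patient_ids, M.item_ids, train, M.level)
    return MaskSplit(masked, frozenset(held), fraction, seed)


def implicit_cost(
    X: np.ndarray, Y: np.ndarray, M: InteractionMatrix, params: ConfidenceParams
) -> float:
    """The confidence-weighted L2 objective at factors (X, Y).

    All cells by default (zeros at confidence 1); ``params.all_cells=False``
    restricts the data term to observed (r > 0) cells.
    """
    if X.shape[0] != M.shape[0] or Y.shape[0] != M.shape[1] or X.shape[1] != Y.shape[1]:
        raise ConfigError(
            f"factor shapes {X.shape}/{Y.shape} do not match interactions {M.shape}"
        )
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise NumericError("non-finite factor values")
    P = M.preferences
    C = 1.0 + params.alpha * M.ratings
    resid2 = (P - X @ Y.T) ** 2
    if params.all_cells:
        data_term = float((C * resid2).sum())
    else:
        obs = M.ratings > 0
        data_term = float((C[obs] * resid2[obs]).sum())
    reg = params.regularization * float((X**2).sum() + (Y**2).sum())
    return data_term + reg


def _solve_side(P: np.ndarray, C: np.ndarray, F: np.ndarray, lam: float) -> np.ndarray:
    """Exact per-row ridge solves for one side, other side's factors F fixed.

    Row u solves (F^T C_u F + lam I) x = F^T C_u p_u, using the standard
    decomposition F^T C_u F = F^T F + F^T (C_u - I) F so only the nonzero
    confidences enter the per-row correction.
    """
    k = F.shape[1]
    FtF = F.T @ F
    out = np.empty((P.shape[0], k))
    eye = np.eye(k)
    for u in range(P.shape[0]):
        cu = C[u]
        extra = cu - 1.0
        nz = np.flatnonzero(extra)
        A = FtF + lam * eye
        if nz.size:
            Fnz = F[nz]
            A = A + (Fnz * extra[nz, None]).T @ Fnz
        b = F.T @ (cu * P[u])
        try:
            out[u] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise NumericError(
                "singular normal equations; use regularization > 0"
            ) from exc
    return out


def als_fit(
    M: InteractionMatrix,
    params: ConfidenceParams,
    mask: Optional[MaskSplit] = None,
) -> "ImplicitALSResults":
    """Functional form of :meth:`ImplicitALS.fit` (train on ``mask.train`` if given)."""
    model = ImplicitALS(mask.train if mask is not None else M, params)
    return model.fit(validation=mask)


class ImplicitALS:
    """Confidence-weighted matrix-factorisation model of a cohort's plans.

    Parameters
    ----------
    interactions : InteractionMatrix
        Training ratings (already masked, if validating).
    params : ConfidenceParams
        alpha, lambda, factor count, sweep budget, seed, tolerance.
    """

    def __init__(self, interactions: InteractionMatrix, params: ConfidenceParams):
        params.validate()
        self.interactions = interactions
        self.params = params

    def fit(self, validation: Optional[MaskSplit] = None) -> "ImplicitALSResults":
        M, params = self.interactions, self.params
        n_u, n_i = M.shape
        rng = np.random.default_rng(params.seed)
        X = 0.01 * rng.standard_normal((n_u, params.n_factors))
        Y = 0.01 * rng.standard_normal((n_i, params.n_factors))
        P = M.preferences
        C = 1.0 + params.alpha * M.ratings
        lam = params.regularization
        # The solver alternates exact minimisations of the all-cells objective;
        # the training log tracks that same objective so it is non-increasing.
        cost_params = params if params.all_cells else replace(params, all_cells=True)

        log = [implicit_cost(X, Y, M, cost_params)]
        for sweep in range(params.n_iterations):
            X = _solve_side(P, C, Y, lam)
            Y = _solve_side(P.T, C.T, X, lam)
            cost = implicit_cost(X, Y, M, cost_params)
            log.append(cost)
            prev = log[-2]
            if prev > 0 and abs(prev - cost) / prev < params.tol:
                logger.debug("converged after %d sweeps (rel change < %g)", sweep + 1, params.tol)
                break
        return ImplicitALSResults(self, X, Y, log, validation)


@dataclass(frozen=True)
class RankedItem:
    code: TreatmentCode
    score: float


class ImplicitALSResults:
    """Fitted factors, training log, and recommendation helpers."""

    def __init__(self, model, user_factors, item_factors, training_log, validation=None):
        self.model = model
        self.user_factors = user_factors
        self.item_factors = item_factors
        self.training_log = list(training_log)
        self.validation = validation

    @property
    def interactions(self) -> InteractionMatrix:
        return self.model.interactions

    def predicted(self) -> np.ndarray:
        """r_hat = X Y^T, the reconstructed preference surface."""
        return self.user_factors @ self.item_factors.T

    def recommend(
        self,
        patient_id: str,
        n: int = 5,
        candidate_set: Optional[Sequence[TreatmentCode]] = None,
        exclude_observed: bool = True,
    ) -> list[RankedItem]:
        """Top-n items for one patient by predicted affinity.

        Ties break by ascending code; training-observed items are removed by
        default so the list holds genuinely new suggestions.
        """
        if n < 1:
            raise ConfigError("n must be >= 1")
        M = self.interactions
        if patient_id not in M.patient_ids:
            raise MissingFeatureError(f"unknown patient {patient_id!r}")
        u = M.patient_ids.index(patient_id)
        scores = self.predicted()[u]
        candidates = list(M.item_ids) if candidate_set is None else list(candidate_set)
        col = {c: j for j, c in enumerate(M.item_ids)}
        ranked = []
        for code in candidates:
            if code not in col:
                raise MissingFeatureError(f"unknown item {code.render()!r}")
            j = col[code]
            if exclude_observed and M.ratings[u, j] > 0:
                continue
            ranked.append(RankedItem(code, float(scores[j])))
        ranked.sort(key=lambda r: (-r.score, r.code))
        return ranked[:n]

    def summary(self) -> pd.DataFrame:
        """Fit diagnostics: shapes, hyperparameters, cost trajectory endpoints."""
        M, p = self.interactions, self.model.params
        rows = [
            ("n_patients", M.shape[0]),
            ("n_items", M.shape[1]),
            ("level", M.level),
            ("sparsity_ratio", round(sparsity_ratio(M), 4)),
            ("n_factors", p.n_factors),
            ("alpha", p.alpha),
            ("regularization", p.regularization),
            ("sweeps_run", len(self.training_log) - 1),
            ("initial_cost", self.training_log[0]),
            ("final_cost", self.training_log[-1]),
        ]
        return pd.DataFrame(rows, columns=["quantity", "value"])


def grid_search_alpha(
    M: InteractionMatrix,
    params: ConfidenceParams,
    alphas: Sequence[float] = (1.0, 10.0, 40.0, 100.0),
    fraction: float = 0.2,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Pick alpha by masked-positive precision@5 on one stratified split.

    Returns the best alpha and the per-alpha score table. A small helper, not
    a full cross-validation: the study itself tuned alpha on its data.
    """
    from .metrics import p_at_k

    split = mask_split(M, fraction, seed)
    rows = []
    for alpha in alphas:
        res = ImplicitALS(split.train, replace(params, alpha=alpha)).fit()
        precs = []
        for u, pid in enumerate(M.patient_ids):
            held_cols = {j for (uu, j) in split.held_out if uu == u}
            if not held_cols:
                continue
            recs = res.recommend(pid, n=5)
            flags = [1 if M.item_ids.index(r.code) in held_cols else 0 for r in recs]
            flags += [0] * (5 - len(flags))
            precs.append(p_at_k(flags, 5))
        rows.append({"alpha": alpha, "masked_p_at_5": float(np.mean(precs)) if precs else 0.0})
    table = pd.DataFrame(rows)
    best = float(table.loc[table.masked_p_at_5.idxmax(), "alpha"])
    return best, table
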
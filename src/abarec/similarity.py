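"""Cosine patient-similarity recommender.

The patient similarity metric (PSM) between two children is the cosine of the
angle between their encoded feature vectors,

    PSM(P1, P2) = P1 . P2 / (||P1|| ||P2||),

where each vector stacks encoded age, encoded gender, the five SRS-2 subscale
T-scores, the SRS-2 total T-score and the VB-MAPP aggregate at intake
(month 0 by default — the cold-start setting where no treatment history
exists yet). For an index child the k = 3 most similar children are retrieved
and their clinician plans aggregated into a ranked list of domain or target
codes, each scored by the summed PSM of the neighbours that carry it.

Encoding before the cosine matters: raw age in months (24-72) would dominate
the inner product, so age and VB-MAPP are min-max scaled to [0, 1] over the
cohort, T-scores are divided by 100, and gender is a 0/1 indicator. Raw and
z-score alternatives are available through :class:`EncodingConfig`.

Model/Results interface::

    res = PatientSimilarityModel(cohort, k=3).fit()
    res.neighbors("P007")            # SimilarityResult
    res.recommend("P007", "domain")  # ranked codes with scores
    res.summary()                    # per-participant neighbour table
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, SRS2_SUBSCALES, TreatmentCode
from .exceptions import (
    ConfigError,
    DimensionMismatchError,
    InsufficientCohortError,
    MissingFeatureError,
    MissingPlanError,
    UndefinedSimilarityError,
)

__all__ = [
    "EncodingConfig",
    "FeatureVector",
    "SimilarityResult",
    "RankedCode",
    "build_feature_vector",
    "build_feature_matrix",
    "psm",
    "top_k_neighbors",
    "recommend_codes",
    "PatientSimilarityModel",
    "PatientSimilarityResults",
]

#: Fixed feature order: age, gender, 5 SRS-2 subscales, SRS-2 total, VB-MAPP.
FEATURE_NAMES = ("age", "gender", *SRS2_SUBSCALES, "srs2_total", "vbmapp")


@dataclass(frozen=True)
class EncodingConfig:
    """How raw fields become vector entries.

    ``scaling='minmax'`` (default): age and VB-MAPP min-max scaled to [0, 1]
    over the cohort, T-scores divided by 100. ``'raw'``: fields used as-is.
    ``'zscore'``: every column standardised over the cohort.
    """

    scaling: str = "minmax"
    timepoint_month: int = 0

    def validate(self) -> None:
        if self.scaling not in ("minmax", "raw", "zscore"):
            raise ConfigError(f"unknown scaling {self.scaling!r}")


@dataclass(frozen=True)
class FeatureVector:
    participant_id: str
    values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SimilarityResult:
    index_id: str
    neighbors: tuple[tuple[str, float], ...]  # (participant_id, psm), scores non-increasing
    k: int


@dataclass(frozen=True)
class RankedCode:
    code: TreatmentCode
    score: float
    supporting_neighbors: tuple[str, ...]


def _raw_row(cohort: Cohort, pid: str, timepoint: int) -> np.ndarray:
    part = next((p for p in cohort.participants if p.id == pid), None)
    if part is None:
        raise MissingFeatureError(f"unknown participant {pid!r}")
    prof = cohort.profile_for(pid, timepoint)
    if prof is None:
        raise MissingFeatureError(
            f"participant {pid!r} has no assessment profile at month {timepoint}"
        )
    if len(prof.srs2_subscale_t) != len(SRS2_SUBSCALES):
        raise MissingFeatureError(
            f"participant {pid!r}: expected {len(SRS2_SUBSCALES)} srs2 subscales"
        )
    for name, val in (("srs2_total", prof.srs2_total_t), ("vbmapp", prof.vbmapp_aggregate)):
        if val is None or (isinstance(val, float) and math.isnan(val)):
            raise MissingFeatureError(name)
    return np.array(
        [
            part.age_months,
            1.0 if part.gender == "male" else 0.0,
            *prof.srs2_subscale_t,
            prof.srs2_total_t,
            prof.vbmapp_aggregate,
        ],
        dtype=float,
    )


def build_feature_matrix(
    cohort: Cohort, config: EncodingConfig = EncodingConfig(), timepoint: Optional[int] = None
) -> tuple[list[str], np.ndarray]:
    """Encoded feature rows for every participant, in cohort order."""
    config.validate()
    tp = config.timepoint_month if timepoint is None else timepoint
    ids = cohort.participant_ids()
    raw = np.vstack([_raw_row(cohort, pid, tp) for pid in ids])
    return ids, _encode(raw, config)


def _encode(raw: np.ndarray, config: EncodingConfig) -> np.ndarray:
    X = raw.astype(float).copy()
    if config.scaling == "raw":
        return X
    if config.scaling == "zscore":
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        return (X - mu) / sd
    # minmax: age (col 0) and vbmapp (last col) to [0,1]; T-scores / 100.
    for col in (0, X.shape[1] - 1):
        lo, hi = X[:, col].min(), X[:, col].max()
        X[:, col] = (X[:, col] - lo) / (hi - lo) if hi > lo else 0.5
    X[:, 2:-1] = X[:, 2:-1] / 100.0
    return X


def build_feature_vector(
    cohort: Cohort, participant_id: str, config: EncodingConfig = EncodingConfig()
) -> FeatureVector:
    """The encoded vector of one participant (cohort context sets the scaling)."""
    ids, mat = build_feature_matrix(cohort, config)
    idx = ids.index(participant_id)
    return FeatureVector(participant_id, tuple(float(v) for v in mat[idx]))


def psm(v1: Sequence[float], v2: Sequence[float]) -> float:
    """Patient similarity metric: cosine of the angle between two vectors."""
    a = np.asarray(v1.values if isinstance(v1, FeatureVector) else v1, dtype=float)
    b = np.asarray(v2.values if isinstance(v2, FeatureVector) else v2, dtype=float)
    if a.shape != b.shape:
        raise DimensionMismatchError(f"vector lengths differ: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedSimilarityError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def top_k_neighbors(
    ids: Sequence[str], matrix: np.ndarray, index_id: str, k: int = 3
) -> SimilarityResult:
    """The k participants most similar to ``index_id`` (index excluded).

    Ties are broken by ascending participant id so results are reproducible.
    """
    ids = list(ids)
    if k >= len(ids):
        raise InsufficientCohortError(
            f"k={k} requires at least {k + 1} participants, cohort has {len(ids)}"
        )
    if index_id not in ids:
        raise MissingFeatureError(f"unknown participant {index_id!r}")
    idx = ids.index(index_id)
    scored = [
        (pid, psm(matrix[idx], matrix[j])) for j, pid in enumerate(ids) if j != idx
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return SimilarityResult(index_id, tuple(scored[:k]), k)


def recommend_codes(
    cohort: Cohort,
    result: SimilarityResult,
    level: str = "domain",
    top_n: Optional[int] = None,
) -> list[RankedCode]:
    """Aggregate the neighbours' plans into one ranked recommendation.

    Candidate codes are the union of the neighbours' codes at ``level``; each
    is scored by the summed PSM of the neighbours whose plan contains it, and
    ranked by score (desc), neighbour count (desc), then code (asc).
    ``top_n=0`` yields an empty recommendation.
    """
    support: dict[TreatmentCode, list[tuple[str, float]]] = {}
    for pid, score in result.neighbors:
        plan = cohort.plan_for(pid)
        if plan is None or not plan.codes(level):
            raise MissingPlanError(f"neighbor {pid!r} has no {level}-level plan")
        for code in plan.codes(level):
            support.setdefault(code, []).append((pid, score))
    ranked = [
        RankedCode(code, sum(s for _, s in sup), tuple(pid for pid, _ in sorted(sup)))
        for code, sup in support.items()
    ]
    ranked.sort(key=lambda r: (-r.score, -len(r.supporting_neighbors), r.code))
    if top_n is not None:
        ranked = ranked[:top_n]
    return ranked


class PatientSimilarityModel:
    """Nearest-neighbour treatment recommender over a validated cohort.

    Parameters
    ----------
    cohort : Cohort
        Participants with intake assessment profiles and clinician plans.
    k : int
        Neighbourhood size; 3 follows the top-three framework.
    encoding : EncodingConfig
        Feature scaling choices.
    """

    def __init__(self, cohort: Cohort, k: int = 3, encoding: EncodingConfig = EncodingConfig()):
        encoding.validate()
        if k < 1:
            raise ConfigError("k must be >= 1")
        self.cohort = cohort
        self.k = k
        self.encoding = encoding

    def fit(self) -> "PatientSimilarityResults":
        ids, mat = build_feature_matrix(self.cohort, self.encoding)
        if self.k >= len(ids):
            raise InsufficientCohortError(
                f"k={self.k} requires at least {self.k + 1} participants"
            )
        neighbors = {pid: top_k_neighbors(ids, mat, pid, self.k) for pid in ids}
        return PatientSimilarityResults(self, ids, mat, neighbors)


class PatientSimilarityResults:
    """Fitted neighbourhoods plus recommendation and reporting helpers."""

    def __init__(self, model, ids, feature_matrix, neighbors):
        self.model = model
        self.ids = ids
        self.feature_matrix = feature_matrix
        self._neighbors = neighbors

    def neighbors(self, participant_id: str) -> SimilarityResult:
        return self._neighbors[participant_id]

    def recommend(
        self, participant_id: str, level: str = "domain", top_n: Optional[int] = None
    ) -> list[RankedCode]:
        return recommend_codes(self.model.cohort, self._neighbors[participant_id], level, top_n)

    def per_neighbor_plans(self, participant_id: str, level: str) -> list[frozenset]:
        """Each neighbour's plan separately (the per-neighbour A/B/C view)."""
        out = []
        for pid, _ in self._neighbors[participant_id].neighbors:
            plan = self.model.cohort.plan_for(pid)
            if plan is None:
                raise MissingPlanError(f"neighbor {pid!r} has no plan")
            out.append(plan.codes(level))
        return out

    def summary(self) -> pd.DataFrame:
        """One row per (participant, neighbour rank): id, neighbour, PSM."""
        rows = []
        for pid in self.ids:
            for rank, (nid, score) in enumerate(self._neighbors[pid].neighbors, start=1):
                rows.append({"participant_id": pid, "rank": rank,
                             "neighbor_id": nid, "psm": score})
        return pd.DataFrame(rows, columns=["participant_id", "rank", "neighbor_id", "psm"])
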
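"""Synthetic cohort generator.

Real assessment and treatment records for the study population are not
publicly available, so this module generates cohorts that carry the one
statistical property every downstream stage relies on: *children with similar
assessment profiles receive overlapping clinician plans, and mastery outcomes
correlate with skill deficits*. The generative model is deliberately the
weakest structure under which both recommenders ought to succeed — a linear
latent-factor model — so that recovery tests are meaningful rather than easy.

Generative model (all randomness from one root seed via named substreams):

1. Demographics: gender ~ Bernoulli(male_fraction); age ~ Uniform(age range).
2. Latent skill deficits: z ~ N(0, I_k) per participant, k latent skills.
   A fixed loading matrix maps latent deficits to the 5 SRS-2 subscales and to
   the domain catalogue.
3. Assessments: subscale T-score = 65 + loading . z + noise, clipped to
   [30, 100]; total T = mean subscale + noise; VB-MAPP = affine *decreasing*
   in mean deficit + noise, clipped to [0, 170] (higher deficit, lower
   milestone score).
4. Plans: a deterministic function of the deficit vector — the plan covers the
   domains whose projected deficit exceeds a threshold (clipped to the plan
   size range, ties to the strongest deficits); within each chosen domain,
   targets 1..t (t in 1..3, growing with the deficit) in ascending order,
   mirroring the easy-to-complex ordering of target codes. Determinism here
   means two children with identical latent deficits get identical plans,
   which is the core assumption the similarity recommender exploits.
5. Mastery: each planned target is mastered with probability decreasing in
   its domain's deficit loading (logistic around ``mastery_base_rate``);
   days-to-mastery is lognormal; month uniform on 1..6.

Defaults mirror the study conditions: 29 participants, 24:5 male:female,
ages 24-72 months, 22 domains, plans spanning 2-8 domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .cohort import (
    AssessmentProfile,
    Cohort,
    MasteryRecord,
    Participant,
    SRS2_SUBSCALES,
    TreatmentCode,
    TreatmentPlan,
)
from .exceptions import ConfigError, DegenerateStructureError

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "neighbor_structure_strength",
    "permutation_pvalue",
    "plan_from_deficit",
    "planted_block_interactions",
]

_SUBSTREAMS = ("demographics", "skills", "plans", "mastery")

#: Projected-deficit threshold above which a domain enters the plan.
_PLAN_DEFICIT_THRESHOLD = 0.5


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort. Defaults are the study conditions."""

    n_participants: int = 29
    male_fraction: float = 24 / 29
    age_range_months: tuple[float, float] = (24.0, 72.0)
    n_domains: int = 22
    targets_per_domain: int = 8
    n_latent_skills: int = 6
    assessment_noise_sd: float = 4.0  # T-score units
    plan_size_range: tuple[int, int] = (2, 8)
    mastery_base_rate: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be positive")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigError("male_fraction must lie in [0, 1]")
        if self.age_range_months[0] >= self.age_range_months[1]:
            raise ConfigError("age_range_months must be an increasing interval")
        if self.n_domains < 1 or self.targets_per_domain < 1 or self.n_latent_skills < 1:
            raise ConfigError("n_domains, targets_per_domain, n_latent_skills must be positive")
        if self.assessment_noise_sd < 0:
            raise ConfigError("assessment_noise_sd must be nonnegative")
        lo, hi = self.plan_size_range
        if not (1 <= lo <= hi):
            raise ConfigError("plan_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_domains:
            raise ConfigError("plan_size_range upper bound exceeds n_domains")
        if not 0.0 <= self.mastery_base_rate <= 1.0:
            raise ConfigError("mastery_base_rate must lie in [0, 1]")


def plan_from_deficit(
    deficit: np.ndarray, spec: CohortSpec
) -> tuple[frozenset, frozenset]:
    """Clinician plan implied by one projected-deficit vector.

    Purely deterministic: the plan covers the domains whose deficit exceeds
    the threshold (count clipped to the plan size range, strongest deficits
    first), with 1-3 targets per domain in ascending (easy-to-complex) order,
    more targets for stronger deficits. Two children with identical deficit
    vectors therefore receive identical plans.
    """
    lo, hi = spec.plan_size_range
    size = int(np.clip(int((deficit > _PLAN_DEFICIT_THRESHOLD).sum()), lo, hi))
    top = np.argsort(-deficit, kind="stable")[:size]
    domains = frozenset(TreatmentCode(int(d) + 1) for d in top)
    targets = set()
    for d in sorted(top):
        dd = deficit[d]
        t_count = 1 + int(dd > _PLAN_DEFICIT_THRESHOLD) + int(dd > 2 * _PLAN_DEFICIT_THRESHOLD)
        for t in range(1, min(t_count, spec.targets_per_domain) + 1):
            targets.add(TreatmentCode(int(d) + 1, t))
    return domains, frozenset(targets)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort from the generative model; deterministic given the seed."""
    spec.validate()
    rng = _substreams(spec.seed)
    n, k = spec.n_participants, spec.n_latent_skills

    # Demographics substream.
    demo = rng["demographics"]
    genders = np.where(demo.random(n) < spec.male_fraction, "male", "female")
    ages = demo.uniform(*spec.age_range_months, size=n)

    # Skills substream: shared loadings, then per-participant deficits.
    sk = rng["skills"]
    subscale_loading = sk.normal(size=(len(SRS2_SUBSCALES), k)) / np.sqrt(k)
    domain_loading = sk.normal(size=(spec.n_domains, k)) / np.sqrt(k)
    z = sk.normal(size=(n, k))

    sd = spec.assessment_noise_sd
    sub_t = 65.0 + 8.0 * z @ subscale_loading.T + sk.normal(scale=sd, size=(n, len(SRS2_SUBSCALES)))
    sub_t = np.clip(sub_t, 30.0, 100.0)
    total_t = np.clip(sub_t.mean(axis=1) + sk.normal(scale=sd / 2 if sd else 0.0, size=n), 30.0, 100.0)
    vbmapp = np.clip(
        85.0 - 30.0 * z.mean(axis=1) + sk.normal(scale=3.0 * sd / 4 if sd else 0.0, size=n),
        0.0, 170.0,
    )

    participants = [
        Participant(id=f"P{i + 1:03d}", age_months=float(ages[i]), gender=str(genders[i]))
        for i in range(n)
    ]
    profiles = [
        AssessmentProfile(
            participant_id=participants[i].id,
            timepoint_month=0,
            srs2_subscale_t=tuple(float(t) for t in sub_t[i]),
            srs2_total_t=float(total_t[i]),
            vbmapp_aggregate=float(vbmapp[i]),
        )
        for i in range(n)
    ]

    # Plans: deterministic in the deficit vector (equal deficits, equal plan).
    deficit = z @ domain_loading.T  # n x n_domains projected deficit
    plans = [
        TreatmentPlan(participants[i].id, *plan_from_deficit(deficit[i], spec))
        for i in range(n)
    ]

    # Mastery substream: probability decreasing in the domain deficit loading.
    ma = rng["mastery"]
    base_logit = logit(np.clip(spec.mastery_base_rate, 1e-6, 1 - 1e-6))
    mastery: list[MasteryRecord] = []
    for i, plan in enumerate(plans):
        for code in sorted(plan.target_codes):
            dom_deficit = deficit[i, code.domain - 1]
            p_master = float(expit(base_logit - 0.8 * dom_deficit))
            mastered = bool(ma.random() < p_master)
            days = float(ma.lognormal(mean=3.0, sigma=0.5)) if mastered else None
            month = int(ma.integers(1, 7))
            mastery.append(MasteryRecord(plan.participant_id, code, mastered, days, month))

    return Cohort(participants, profiles, plans, mastery)


def _pairwise_arrays(cohort: Cohort, timepoint: int) -> tuple[np.ndarray, np.ndarray]:
    """Condensed pairwise cosine similarities and the plan-membership matrix.

    Returns (sims, B): sims is the upper-triangle cosine similarity of the
    encoded feature vectors; B is the participants x domains binary plan
    membership used to form Jaccard overlaps.
    """
    from .similarity import EncodingConfig, build_feature_matrix

    with_plans = [p for p in cohort.participants if cohort.plan_for(p.id) is not None]
    if len(with_plans) < 3:
        raise DegenerateStructureError("need at least 3 participants with plans")
    sub = Cohort(with_plans, cohort.profiles, cohort.plans, cohort.mastery)
    ids, mat = build_feature_matrix(sub, EncodingConfig(), timepoint=timepoint)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    if (norms == 0).any():
        raise DegenerateStructureError("zero-norm feature vector")
    unit = mat / norms
    cos = unit @ unit.T
    iu = np.triu_indices(len(ids), k=1)

    domains = sorted({c for pid in ids for c in sub.plan_for(pid).domain_codes})
    col = {c: j for j, c in enumerate(domains)}
    B = np.zeros((len(ids), len(domains)))
    for i, pid in enumerate(ids):
        for c in sub.plan_for(pid).domain_codes:
            B[i, col[c]] = 1.0
    return cos[iu], B


def _jaccard_condensed(B: np.ndarray) -> np.ndarray:
    inter = B @ B.T
    sizes = B.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    iu = np.triu_indices(B.shape[0], k=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)
    return jac[iu]


def neighbor_structure_strength(cohort: Cohort, timepoint: int = 0) -> float:
    """Rank correlation between assessment similarity and plan overlap.

    For every participant pair, computes cosine similarity of the intake
    feature vectors and Jaccard overlap of domain-code sets, and returns the
    Spearman correlation between the two pairwise lists. Positive values mean
    the cohort carries the structure similarity-based recommendation needs.

    Raises :class:`DegenerateStructureError` when either list is constant
    (e.g. all plans identical).
    """
    sims, B = _pairwise_arrays(cohort, timepoint)
    overlaps = _jaccard_condensed(B)
    if np.ptp(sims) == 0 or np.ptp(overlaps) == 0:
        raise DegenerateStructureError(
            "pairwise similarity or plan overlap is constant; correlation undefined"
        )
    rho = stats.spearmanr(sims, overlaps).statistic
    return float(rho)


def permutation_pvalue(
    cohort: Cohort, n_permutations: int = 199, seed: int = 0, timepoint: int = 0
) -> tuple[float, float]:
    """Observed structure strength and a permutation p-value for it.

    Plans are shuffled across participants (feature vectors stay put); the
    p-value is the fraction of shuffles whose statistic is at least the
    observed one, with the +1 correction.
    """
    sims, B = _pairwise_arrays(cohort, timepoint)
    overlaps = _jaccard_condensed(B)
    if np.ptp(sims) == 0 or np.ptp(overlaps) == 0:
        raise DegenerateStructureError("correlation undefined on degenerate cohort")
    observed = float(stats.spearmanr(sims, overlaps).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm_overlaps = _jaccard_condensed(B[rng.permutation(B.shape[0])])
        if np.ptp(perm_overlaps) == 0:  # pragma: no cover - pathological shuffle
            count += 1
            continue
        if stats.spearmanr(sims, perm_overlaps).statistic >= observed:
            count += 1
    pvalue = (count + 1) / (n_permutations + 1)
    return observed, pvalue


def planted_block_interactions(
    n_users: int = 200,
    n_blocks: int = 4,
    items_per_block: int = 10,
    positives_per_user: int = 5,
    rating: float = 5.0,
    seed: int = 0,
):
    """Exactly low-rank patient x item interactions with planted block structure.

    Users belong to one of ``n_blocks`` groups; each user holds
    ``positives_per_user`` random positives inside their own item block and
    none elsewhere. A factorisation with ``n_blocks`` factors can separate
    the blocks essentially perfectly; what it cannot do is distinguish a
    held-out positive from a never-owned item of the same block,
    which bounds achievable masked-item precision at
    ``top_n / (items_per_block - positives_per_user + 1)``.

    Returns an :class:`~abarec.als.InteractionMatrix` whose item codes are
    ``block.slot`` treatment codes.
    """
    from .als import InteractionMatrix

    if positives_per_user >= items_per_block:
        raise ConfigError("positives_per_user must be < items_per_block")
    rng = np.random.default_rng(seed)
    n_items = n_blocks * items_per_block
    codes = tuple(
        TreatmentCode(1 + j // items_per_block, 1 + j % items_per_block)
        for j in range(n_items)
    )
    R = np.zeros((n_users, n_items))
    for u in range(n_users):
        g = u % n_blocks
        cols = rng.choice(
            np.arange(g * items_per_block, (g + 1) * items_per_block),
            size=positives_per_user, replace=False,
        )
        R[u, cols] = rating
    ids = tuple(f"U{u + 1:04d}" for u in range(n_users))
    return InteractionMatrix(ids, codes, R, "target")
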
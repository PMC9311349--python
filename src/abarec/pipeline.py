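"""End-to-end study pipeline: simulate -> recommend (both models) -> evaluate.

:func:`run_experiment` reproduces the study's reporting surface on a cohort
(synthetic by default): per-participant commonality tables for both
recommenders, month-window treatment-effectiveness tables, per-neighbour
psychometrics for the similarity model, rank-aware metrics (P@5, MAP@5,
NDCG@5) for the collaborative-filtering model, and a manifest tying every
number to parameters and seeds. Reports are plain CSV/JSON and contain no
timestamps, so a fixed root seed yields byte-identical bundles; wall-clock
timing goes to the logging stream only.

:func:`reproduce_fixture_summaries` recomputes the packaged result tables'
column means and reports the absolute difference against the printed
average rows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .als import (
    ConfidenceParams,
    DOMAIN_PARAMS,
    TARGET_PARAMS,
    ImplicitALS,
    build_interactions,
    mask_split,
    sparsity_ratio,
)
from .cohort import Cohort, read_cohort, validate_cohort, write_cohort
from .exceptions import AbarecError, ConfigError, UndefinedMetricError
from .fixtures import PRINTED_AVERAGES, PRINTED_TOTAL_LEARNERS, load_fixture_table
from .metrics import (
    ap_at_k,
    classification_metrics,
    commonality,
    confusion_counts,
    map_at_k,
    ndcg_at_k,
    p_at_k,
    roc_auc,
    treatment_effectiveness,
)
from .similarity import EncodingConfig, PatientSimilarityModel
from .simulate import CohortSpec, generate_cohort

__all__ = ["ExperimentConfig", "StageError", "run_experiment", "reproduce_fixture_summaries"]

logger = logging.getLogger(__name__)

TE_WINDOWS = ((1, 3), (4, 6), (1, 6))


class StageError(AbarecError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment run needs, seeded from one root seed."""

    cohort_spec: Optional[CohortSpec] = None     # synthetic source ...
    cohort_path: Optional[str] = None            # ... or files on disk
    similarity_k: int = 3
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    domain_params: ConfidenceParams = DOMAIN_PARAMS
    target_params: ConfidenceParams = TARGET_PARAMS
    mask_fraction: float = 0.2
    top_n: int = 5
    eval_k: int = 5
    commonality_mode: str = "precision"
    seed: int = 0

    def validate(self) -> None:
        if (self.cohort_spec is None) == (self.cohort_path is None):
            raise ConfigError("exactly one of cohort_spec / cohort_path must be set")
        if self.similarity_k < 1 or self.top_n < 1 or self.eval_k < 1:
            raise ConfigError("similarity_k, top_n and eval_k must be >= 1")
        # mask_fraction is checked by mask_split inside the CF stage, so a bad
        # fraction aborts there with the stage name attached.


def _similarity_psychometrics(cohort: Cohort, results, level: str, k: int) -> pd.DataFrame:
    """Per-neighbour-rank confusion psychometrics plus a PSM-score AUC.

    For neighbour rank r, each participant's "recommendation" is that
    neighbour's plan; the universe is every code at the level observed in the
    cohort. The AUC ranks candidate codes by summed-PSM score with relevance
    = membership in the participant's own plan (participants whose candidate
    set is single-class are skipped for AUC).
    """
    universe = {c for plan in cohort.plans for c in plan.codes(level)}
    per_rank: dict[int, dict[str, list[float]]] = {
        r: {"precision": [], "recall": [], "accuracy": [], "f1": []} for r in range(k)
    }
    aucs: list[float] = []
    for pid in cohort.participant_ids():
        truth = cohort.plan_for(pid).codes(level)
        neighbor_plans = results.per_neighbor_plans(pid, level)
        for r, rec in enumerate(neighbor_plans):
            try:
                m = classification_metrics(confusion_counts(rec, truth, universe))
            except UndefinedMetricError:
                continue
            for key, val in m.items():
                per_rank[r][key].append(val)
        ranked = results.recommend(pid, level)
        labels = [1 if rc.code in truth else 0 for rc in ranked]
        if 0 < sum(labels) < len(labels):
            aucs.append(roc_auc([rc.score for rc in ranked], labels))
    rows = []
    for r in range(k):
        row = {"neighbor_rank": r + 1}
        row.update({key: float(np.mean(vals)) if vals else float("nan")
                    for key, vals in per_rank[r].items()})
        row["auc"] = float(np.mean(aucs)) if aucs else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def _rank_metrics(M, split, res, k: int) -> dict[str, float]:
    """P@k / MAP@k / NDCG@k of top-k lists against the held-out positives."""
    precs, aps, ndcgs = [], [], []
    for u, pid in enumerate(M.patient_ids):
        held_cols = {j for (uu, j) in split.held_out if uu == u}
        if not held_cols:
            continue
        recs = res.recommend(pid, n=k)
        flags = [1 if M.item_ids.index(r.code) in held_cols else 0 for r in recs]
        flags += [0] * (k - len(flags))
        precs.append(p_at_k(flags, k))
        aps.append(ap_at_k(flags, k, m=len(held_cols)))
        ndcgs.append(ndcg_at_k(flags, k))
    if not precs:
        raise UndefinedMetricError("no user has held-out positives to evaluate")
    return {
        f"p_at_{k}": float(np.mean(precs)),
        f"map_at_{k}": map_at_k(aps),
        f"ndcg_at_{k}": float(np.mean(ndcgs)),
    }


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write the report bundle under ``out_dir``.

    Returns the metric summary dict. On a stage failure the partial bundle is
    flagged invalid in ``manifest.json`` and :class:`StageError` is raised.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config),
        "status": "running",
    }
    stage = "init"
    try:
        # ---- stage: cohort -------------------------------------------------
        stage = "cohort"
        t0 = time.perf_counter()
        if config.cohort_spec is not None:
            spec = dataclasses.replace(config.cohort_spec, seed=config.seed)
            cohort = generate_cohort(spec)
            write_cohort(cohort, out / "cohort")
        else:
            cohort = read_cohort(config.cohort_path)
        violations = validate_cohort(cohort)
        if violations:
            raise ConfigError(f"cohort failed validation: {violations[:3]} ...")
        logger.info("stage cohort: n=%d participants (%.2fs)",
                    len(cohort), time.perf_counter() - t0)

        # ---- stage: similarity --------------------------------------------
        stage = "similarity"
        t0 = time.perf_counter()
        sim_res = PatientSimilarityModel(cohort, config.similarity_k, config.encoding).fit()
        sim_rows, sim_common = [], {"domain": [], "target": []}
        for pid in cohort.participant_ids():
            for level in ("domain", "target"):
                ranked = sim_res.recommend(pid, level)
                truth = cohort.plan_for(pid).codes(level)
                rec_codes = [rc.code for rc in ranked]
                sim_common[level].append(
                    commonality(set(rec_codes), truth, config.commonality_mode)
                )
                for rank, rc in enumerate(ranked, 1):
                    sim_rows.append({
                        "index_id": pid, "level": level, "rank": rank,
                        "code": rc.code.render(), "score": round(rc.score, 10),
                        "supporting_neighbor_ids": ";".join(rc.supporting_neighbors),
                    })
        pd.DataFrame(sim_rows).to_csv(out / "similarity_recs.csv", index=False)
        sim_psy = {
            level: _similarity_psychometrics(cohort, sim_res, level, config.similarity_k)
            for level in ("domain", "target")
        }
        for level, df in sim_psy.items():
            df.to_csv(out / f"similarity_psychometrics_{level}.csv", index=False)
        logger.info("stage similarity done (%.2fs)", time.perf_counter() - t0)

        # ---- stage: collaborative filtering -------------------------------
        stage = "collaborative_filtering"
        t0 = time.perf_counter()
        cf_rows, cf_common = [], {"domain": [], "target": []}
        cf_rank_metrics, cf_sparsity = {}, {}
        cf_recs_by_level: dict[str, dict[str, list]] = {}
        for level, params in (("domain", config.domain_params),
                              ("target", config.target_params)):
            M = build_interactions(cohort, level)
            cf_sparsity[level] = sparsity_ratio(M)
            logger.info("CF %s interactions %s, sparsity %.3f",
                        level, M.shape, cf_sparsity[level])
            split = mask_split(M, config.mask_fraction, seed=config.seed)
            params = dataclasses.replace(params, seed=config.seed)
            res = ImplicitALS(split.train, params).fit(validation=split)
            cf_rank_metrics[level] = _rank_metrics(M, split, res, config.eval_k)
            cf_recs_by_level[level] = {}
            for pid in M.patient_ids:
                recs = res.recommend(pid, n=config.top_n)
                cf_recs_by_level[level][pid] = [r.code for r in recs]
                truth = cohort.plan_for(pid).codes(level)
                if recs:
                    cf_common[level].append(
                        commonality({r.code for r in recs}, truth, config.commonality_mode)
                    )
                for rank, r in enumerate(recs, 1):
                    cf_rows.append({
                        "index_id": pid, "level": level, "rank": rank,
                        "code": r.code.render(), "score": round(r.score, 10),
                    })
        pd.DataFrame(cf_rows).to_csv(out / "cf_recs.csv", index=False)
        logger.info("stage collaborative_filtering done (%.2fs)", time.perf_counter() - t0)

        # ---- stage: effectiveness ------------------------------------------
        stage = "effectiveness"
        te_rows = []
        for pid in cohort.participant_ids():
            mastery = cohort.mastery_for(pid)
            row: dict = {"participant_id": pid}
            for model_name in ("similarity", "cf"):
                for level in ("domain", "target"):
                    if model_name == "similarity":
                        rec = [rc.code for rc in sim_res.recommend(pid, level)]
                    else:
                        rec = cf_recs_by_level[level].get(pid, [])
                    for lo, hi in TE_WINDOWS:
                        key = f"{model_name}_{level}_m{lo}_{hi}"
                        try:
                            row[key] = treatment_effectiveness(rec, mastery, (lo, hi))
                        except UndefinedMetricError:
                            row[key] = float("nan")
            te_rows.append(row)
        te_table = pd.DataFrame(te_rows)
        te_table.to_csv(out / "effectiveness.csv", index=False)

        # ---- stage: report -------------------------------------------------
        stage = "report"
        summary = {
            "n_participants": len(cohort),
            "similarity": {
                "commonality_mode": config.commonality_mode,
                "mean_commonality_domain": float(np.mean(sim_common["domain"])),
                "mean_commonality_target": float(np.mean(sim_common["target"])),
            },
            "collaborative_filtering": {
                "commonality_mode": config.commonality_mode,
                "mean_commonality_domain": float(np.mean(cf_common["domain"])),
                "mean_commonality_target": float(np.mean(cf_common["target"])),
                "sparsity_ratio": {k: float(v) for k, v in cf_sparsity.items()},
                **{f"{lvl}_{k}": v for lvl, d in cf_rank_metrics.items()
                   for k, v in d.items()},
            },
            "effectiveness_means": {
                c: float(te_table[c].mean()) for c in te_table.columns
                if c != "participant_id"
            },
        }
        (out / "metrics_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        manifest["status"] = "ok"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return summary
    except Exception as exc:
        manifest["status"] = "invalid"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        logger.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def reproduce_fixture_summaries() -> pd.DataFrame:
    """Recompute every packaged table's summary arithmetic.

    One row per comparison: column mean vs the printed average, plus the
    enrollment-count total. ``abs_diff`` <= 0.01 everywhere on an intact
    install (printed values are rounded to at most two decimals).
    """
    rows = []
    for (table_id, column), printed in sorted(PRINTED_AVERAGES.items()):
        tab = load_fixture_table(table_id)
        recomputed = float(tab.numeric_column(column).mean())
        rows.append({
            "table": table_id, "column": column, "recomputed": recomputed,
            "printed": printed, "abs_diff": abs(recomputed - printed),
        })
    t1 = load_fixture_table("table1")
    total = float(t1.numeric_column("Number of learners").sum())
    rows.append({
        "table": "table1", "column": "Number of learners (sum)",
        "recomputed": total, "printed": float(PRINTED_TOTAL_LEARNERS),
        "abs_diff": abs(total - PRINTED_TOTAL_LEARNERS),
    })
    return pd.DataFrame(rows)
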
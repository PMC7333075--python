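"""End-to-end orchestration: simulate -> extract -> cluster -> evaluate.

One :class:`RunConfig` drives the whole screening experiment; every stage
consumes only artifacts produced by earlier stages, all randomness fans out
from the single config seed, and re-running the same config reproduces the
outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import replay_model, synthetic_sim, tsclust
from .replay_model import CohortRecord, DriveRecording, truncate_at_motion
from .screen_eval import FAIL_THRESHOLD, logistic_sweep, svm_grid
from .synthetic_sim import Environment, SimParams
from .tsclust import DissimilarityMatrix, best_clustering
from .variables_features import build_variables_table, zone_collision_flags
from .zone_partition import Subinterval, extract_subintervals

__all__ = ["RunConfig", "run_pipeline", "prepare_dissimilarities",
           "trainfold_feature_builder", "fail_labels"]

log = logging.getLogger("zonescreen")


@dataclass
class RunConfig:
    """Fully resolved configuration of one screening run."""

    seed: int = 7
    n_drivers: int = 200
    n_env: int = 10
    total_zones: int = 166
    k: int = 8
    restarts: int = 20
    max_iter: int = 100
    cluster_scope: str = "trainfold"        # "all" | "trainfold"
    dtw_normalization: str = "normalized"   # "raw" | "normalized"
    classifier: str = "logistic"            # "logistic" | "svm"
    folds: int = 10
    out_dir: str = "zonescreen_run"
    # simulator conditions
    route_length: float = 5200.0
    zone_scale: float = 1.0
    noise_sigma: float = 0.05
    a: float = 34.0
    b: float = 0.01
    sigma_e: float = 8.0
    write_replays: bool = True

    def __post_init__(self) -> None:
        for name in ("n_drivers", "n_env", "total_zones", "k", "restarts",
                     "max_iter", "folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.cluster_scope not in ("all", "trainfold"):
            raise ValueError(f"invalid cluster_scope {self.cluster_scope!r}")
        if self.dtw_normalization not in ("raw", "normalized"):
            raise ValueError(f"invalid dtw_normalization {self.dtw_normalization!r}")
        if self.classifier not in ("logistic", "svm"):
            raise ValueError(f"invalid classifier {self.classifier!r}")

    def sim_params(self) -> SimParams:
        return SimParams(noise_sigma=self.noise_sigma, a=self.a, b=self.b,
                         sigma_e=self.sigma_e)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def fail_labels(records: list[CohortRecord]) -> pd.Series:
    """Boolean fail labels (score >= 26) indexed by drive id."""
    return pd.Series({r.drive_id: r.ore_score >= FAIL_THRESHOLD
                      for r in records}, name="fail")


def prepare_dissimilarities(
    recordings: list[DriveRecording],
    envs: list[Environment],
    normalized: bool = True,
) -> tuple[dict[int, DissimilarityMatrix], dict[int, list[Subinterval]]]:
    """Truncate, partition and standardize drives; DTW matrix per zone.

    Channels are z-scored per zone using pooled statistics over all of that
    zone's subintervals before the (single) all-pairs DTW computation.
    """
    env_by_id = {e.environment_id: e for e in envs}
    subs_by_zone: dict[int, list[Subinterval]] = {}
    for rec in recordings:
        env = env_by_id[rec.environment_id]
        rec = truncate_at_motion(rec)
        for sub in extract_subintervals(rec, env):
            subs_by_zone.setdefault(sub.zone_id, []).append(sub)
    D_by_zone: dict[int, DissimilarityMatrix] = {}
    for zone_id in sorted(subs_by_zone):
        subs = subs_by_zone[zone_id]
        if len(subs) < 2:
            continue
        std_subs, _ = tsclust.standardize_subintervals(subs)
        D_by_zone[zone_id] = tsclust.dissimilarity_matrix(
            std_subs, normalized=normalized)
    return D_by_zone, subs_by_zone


def trainfold_feature_builder(
    D_by_zone: dict[int, DissimilarityMatrix],
    k: int, restarts: int, max_iter: int, seed: int,
):
    """Feature builder that re-elects medoids on each training fold.

    Clustering sees only the training-fold submatrix of each zone; the
    feature for any drive is then its dissimilarity to those training-fold
    medoids, read off the precomputed full matrix.  Zones with fewer
    training subintervals than k use as many medoids as available.
    """
    def build(train_ids: pd.Index) -> pd.DataFrame:
        train_set = set(train_ids)
        all_ids: list[str] = []
        seen: set[str] = set()
        for zone_id in sorted(D_by_zone):
            for did in D_by_zone[zone_id].ids:
                if did not in seen:
                    seen.add(did)
                    all_ids.append(did)
        blocks = []
        for zone_id in sorted(D_by_zone):
            D = D_by_zone[zone_id]
            pos = [i for i, did in enumerate(D.ids) if did in train_set]
            k_eff = min(k, len(pos))
            if k_eff < 1:
                continue
            sub = DissimilarityMatrix(
                values=D.values[np.ix_(pos, pos)],
                ids=[D.ids[i] for i in pos])
            zone_seed = int(np.random.SeedSequence([seed, zone_id])
                            .generate_state(1)[0] % (2**31 - 1))
            model = best_clustering(sub, k=k_eff, restarts=restarts,
                                    max_iter=max_iter, seed=zone_seed)
            medoids_global = np.array([pos[m] for m in model.medoid_ids])
            cols = [f"zone{zone_id}_m{j}" for j in range(k_eff)]
            block = pd.DataFrame(np.nan, index=pd.Index(all_ids), columns=cols)
            block.loc[D.ids, :] = D.values[:, medoids_global]
            blocks.append(block)
        return pd.concat(blocks, axis=1)

    return build


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write artifacts under ``config.out_dir``.

    Returns a run report with stage timings and headline metrics.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}

    def stage(name):
        t0 = time.perf_counter()

        def done():
            dt = time.perf_counter() - t0
            report["stages"][name] = round(dt, 3)
            log.info("stage %s finished in %.2f s", name, dt)
        return done

    # --- simulate -----------------------------------------------------
    end = stage("simulate")
    envs = synthetic_sim.generate_environment_bank(
        n_env=config.n_env, total_zones=config.total_zones, seed=config.seed,
        route_length=config.route_length, zone_scale=config.zone_scale)
    synthetic_sim.save_environments(envs, out / "environments.json")
    recordings, records = synthetic_sim.generate_cohort(
        config.n_drivers, envs, params=config.sim_params(), seed=config.seed)
    replay_model.write_cohort_csv(records, out / "cohort.csv")
    if config.write_replays:
        replay_dir = out / "replays"
        replay_dir.mkdir(exist_ok=True)
        for rec in recordings:
            replay_model.write_replay(rec, replay_dir / f"{rec.drive_id}.jsonl")
    end()

    # --- extract + dissimilarities ------------------------------------
    end = stage("extract")
    D_by_zone, subs_by_zone = prepare_dissimilarities(
        recordings, envs, normalized=config.dtw_normalization == "normalized")
    end()

    # --- cluster (full-data models, for inspection/reporting) ---------
    end = stage("cluster")
    models = tsclust.cluster_zones(D_by_zone, k=config.k,
                                   restarts=config.restarts,
                                   max_iter=config.max_iter, seed=config.seed)
    scores = {r.drive_id: r.ore_score for r in records}
    env_by_id = {e.environment_id: e for e in envs}
    coll_by_zone: dict[int, dict[str, bool]] = {}
    for rec in recordings:
        flags = zone_collision_flags(rec, env_by_id[rec.environment_id])
        for zid, flag in flags.items():
            coll_by_zone.setdefault(zid, {})[rec.drive_id] = flag
    for zid, model in models.items():
        tsclust.summarize_clusters(model, ore_scores=scores,
                                   collision_flags=coll_by_zone.get(zid, {}))
    tsclust.save_models(models, out / "cluster_models.json")
    features = tsclust.membership_features(D_by_zone, models)
    features.to_csv(out / "membership_features.csv")
    end()

    # --- variables feature set ----------------------------------------
    end = stage("featurize_variables")
    variables = build_variables_table(
        [truncate_at_motion(r) for r in recordings], envs)
    variables.to_csv(out / "variables.csv")
    end()

    # --- evaluate ------------------------------------------------------
    end = stage("evaluate")
    labels = fail_labels(records).loc[features.index]
    if config.classifier == "logistic":
        builder = None
        feats = features
        if config.cluster_scope == "trainfold":
            builder = trainfold_feature_builder(
                D_by_zone, config.k, config.restarts, config.max_iter,
                config.seed)
            feats = None
        sweep = logistic_sweep(feats, labels, folds=config.folds,
                               seed=config.seed, feature_builder=builder)
        rows = []
        for tau, cm, m in zip(sweep.thresholds, sweep.confusions, sweep.metrics):
            rows.append({"threshold": tau, "FF": cm.FF, "FP": cm.FP,
                         "PF": cm.PF, "PP": cm.PP,
                         "accuracy": m.accuracy, "fail_rate": m.fail_rate,
                         "false_alarm_rate": m.false_alarm_rate,
                         "ratio_false_alarms": m.ratio_false_alarms,
                         "tpr": m.tpr, "fpr": m.fpr, "rr": m.rr,
                         "rr_lo": m.rr_ci[0], "rr_hi": m.rr_ci[1]})
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        pd.DataFrame(sweep.roc.points,
                     columns=["fpr", "tpr", "threshold"]).to_csv(
            out / "roc_points.csv", index=False)
        accs = [m.accuracy for m in sweep.metrics]
        report["auc"] = sweep.roc.auc
        report["best_accuracy"] = float(np.nanmax(accs))
        report["best_threshold"] = float(
            sweep.thresholds[int(np.nanargmax(accs))])
    else:
        surface = svm_grid(features, labels, folds=config.folds,
                           seed=config.seed)
        surface.to_csv(out / "metrics.csv", index=False)
        report["best_accuracy"] = float(surface["accuracy"].max())
    end()

    report["n_drivers"] = config.n_drivers
    report["n_zones"] = len(D_by_zone)
    report["feature_width"] = int(features.shape[1])
    report["prevalence"] = float(labels.mean())
    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
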
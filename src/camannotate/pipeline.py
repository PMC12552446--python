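"""End-to-end orchestration: simulate or ingest, classify, evaluate.

A run is fully specified by a :class:`RunConfig`; outputs land in one run
directory with a manifest recording the config hash, seeds and per-stage
row counts.  Splits are assigned at the participant level — the unit of
generalisation in camera validation studies — never at the image level,
and evaluation is restricted to participants outside any tuning-flagged
stage (here: the held-out test split).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotations import (INTENSITY_CLASSES, annotate_table, capture_stats,
                          estimate_time_covered, summarize_study)
from .metrics import (metrics_table, per_participant_metrics, quartile_plot,
                      stratified_metrics, summarize_metric)
from .quality import darkness_percentile_flags
from .simulate import StudyConfig, generate_descriptions, generate_study
from .zeroshot import ZeroShotIntensityClassifier


def split_participants(participant_ids, fractions=(0.70, 0.15, 0.15),
                       seed: int = 0, names=("train", "val", "test")) -> dict:
    """Deterministic participant-level split assignment.

    Sizes are floors of fraction * n; the rounding remainder goes to the
    first (training) split.  Participants are shuffled with the seed, so
    the same ids and seed always give the same assignment.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != len(names):
        raise ValueError("one fraction per split name")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    ids = sorted(set(participant_ids))
    if not ids:
        return {}
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(ids))
    n = len(order)
    sizes = [int(np.floor(f * n)) for f in fractions]
    sizes[0] += n - sum(sizes)
    assignment = {}
    cursor = 0
    for name, size in zip(names, sizes):
        for pid in order[cursor:cursor + size]:
            assignment[pid] = name
        cursor += size
    return assignment


@dataclass
class RunConfig:
    """One reproducible synthetic run of the full pipeline."""
    out_dir: str
    seed: int = 0
    study: StudyConfig = field(default_factory=StudyConfig)
    mode: str = "clean_label"            # retrieval target mode
    noise_rate: float = 0.0              # describer substitution noise
    split_fractions: tuple = (0.70, 0.15, 0.15)
    darkness_percentile: float = 5.0
    epoch_length_s: float = 60.0
    make_plots: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(_as_jsonable(dataclasses.asdict(self)),
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _as_jsonable(dataclasses.asdict(obj))
    return obj


def _met_table_from_catalogue(catalogue) -> dict:
    table = {}
    for a in catalogue:
        entry = {"met": a.met, "posture": a.posture}
        table[a.code] = entry
        table[a.label] = entry
    return table


def evaluate_predictions(joined: pd.DataFrame,
                         stratum_col: str | None = None) -> dict:
    """Per-participant metrics plus five-number summaries (and optional
    stratified metrics) from a joined truth/prediction table."""
    metrics = per_participant_metrics(joined)
    summaries = {"kappa": summarize_metric(metrics, "kappa"),
                 "accuracy": summarize_metric(metrics, "accuracy")}
    for c in INTENSITY_CLASSES:
        summaries[f"f1_{c}"] = summarize_metric(metrics, "f1", c)
    out = {"metrics": metrics, "summaries": summaries}
    if stratum_col is not None and stratum_col in joined.columns:
        out["stratified"] = stratified_metrics(joined, stratum_col)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> ingest -> classify -> evaluate, writing tables,
    summaries and a manifest to the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = dataclasses.replace(config.study, seed=config.seed)
    counts = {}

    # --- simulate -----------------------------------------------------
    annotations, truth = generate_study(study)
    annotations.to_csv(out / "annotations.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    counts["simulate"] = len(annotations)

    # --- ingest + study summary --------------------------------------
    met_table = _met_table_from_catalogue(study.catalogue)
    ingested = annotate_table(annotations, met_table,
                              study.unknown_vocabulary)
    ingested.to_csv(out / "annotations_ingested.csv", index=False)
    summary = summarize_study(ingested)
    per_pid_stats = [capture_stats(g["timestamp"].to_numpy(), participant_id=p)
                     for p, g in ingested.groupby("participant_id")]
    medians = [s.delta_t_median for s in per_pid_stats
               if s.delta_t_median is not None]
    if medians:
        study_median_dt = float(np.median(medians))
        coverage = estimate_time_covered(summary["n_labelled"],
                                         study_median_dt)
        summary["median_delta_t_s"] = study_median_dt
        summary["time_covered_h"] = coverage.hours
        summary["time_covered_h_exact"] = coverage.hours_exact
    with open(out / "summary.json", "w") as fh:
        json.dump(_as_jsonable(summary), fh, indent=2)
    counts["ingest"] = len(ingested)

    # --- split (participant-level) -----------------------------------
    split = split_participants(annotations["participant_id"],
                               config.split_fractions, seed=config.seed)
    with open(out / "split.json", "w") as fh:
        json.dump(split, fh, indent=2)
    test_pids = {p for p, s in split.items() if s == "test"}

    # --- describe + classify -----------------------------------------
    descriptions = generate_descriptions(truth, study.catalogue,
                                         noise_rate=config.noise_rate,
                                         seed=config.seed + 1)
    descriptions.to_csv(out / "descriptions.csv", index=False)
    clf = ZeroShotIntensityClassifier(mode=config.mode)
    if config.mode == "clean_label":
        clf.fit([a.label for a in study.catalogue],
                [a.intensity for a in study.catalogue])
    else:
        clf.fit()
    predictions = clf.predict_records(
        descriptions["description"],
        participant_ids=descriptions["participant_id"],
        timestamps=descriptions["timestamp"])
    predictions.to_csv(out / "predictions.csv", index=False)
    counts["classify"] = len(predictions)

    # --- evaluate (held-out participants only) -----------------------
    joined = truth.merge(
        predictions[["participant_id", "timestamp", "predicted_intensity"]],
        on=["participant_id", "timestamp"])
    joined = joined.rename(columns={"intensity": "truth",
                                    "predicted_intensity": "pred"})
    eval_table = joined[joined["participant_id"].isin(test_pids)].copy()
    # leakage guard: evaluation participants never overlap tuning splits
    assert set(eval_table["participant_id"]) <= test_pids
    dark_flags = darkness_percentile_flags(eval_table["brightness"],
                                           config.darkness_percentile)
    eval_table["dark_stratum"] = np.where(dark_flags, "dark", "bright")
    result = evaluate_predictions(eval_table, stratum_col="dark_stratum")
    metrics_table(result["metrics"]).to_csv(out / "metrics.csv", index=False)
    with open(out / "metrics_summary.json", "w") as fh:
        json.dump({k: (dataclasses.asdict(s) if s is not None else None)
                   for k, s in result["summaries"].items()}, fh, indent=2)
    counts["evaluate"] = len(eval_table)
    if config.make_plots:
        quartile_plot({c: result["summaries"][f"f1_{c}"]
                       for c in INTENSITY_CLASSES},
                      out / "f1_quartiles.png", title="per-participant F1")

    # --- manifest -----------------------------------------------------
    manifest = {
        "package_version": __version__,
        "config": _as_jsonable(dataclasses.asdict(config)),
        "config_hash": config.config_hash(),
        "row_counts": counts,
        "n_participants_by_split": {s: sum(1 for v in split.values() if v == s)
                                    for s in ("train", "val", "test")},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
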
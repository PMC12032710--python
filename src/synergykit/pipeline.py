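"""End-to-end orchestration: simulate -> preprocess -> extract -> select ->
match -> FWHM -> support statistics.

A run is fully determined by its configuration and seed; the run directory
holds a config snapshot, every stage's artifacts, and a machine-readable
``summary.json`` with the selected model orders, the compactness table, the
cluster map, the FWHM table, and the statistics tables.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as skio
from .datatypes import ProcessedTrial, SUPPORTS
from .extraction import (
    FoldError,
    SelectionError,
    StrategyDataset,
    build_strategy_dataset,
    compactness_summary,
    compare_model_counts,
    cross_validated_curve,
    extract_synergies,
    select_n_knee,
    select_n_star,
)
from .matching import find_min_valid_k, robustness_check
from .preprocessing import normalize_amplitude, preprocess_participant
from .stats import run_support_analysis
from .synthetic import GeneratorConfig, generate_cohort, make_ground_truth
from .timing import fwhm_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | Path = "run"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    level: str = "raw"             # 'raw' (full preprocessing) or 'envelope'
    n_max: int = 30
    n_folds: int = 5
    restarts: int = 50
    max_iter: int = 3000
    match_repeats: int = 10
    alpha: float = 0.05
    skip_ecg: bool = False
    ecg_min_duration_s: float = 30.0
    write_artifacts: bool = True


def _processed_from_envelope(trial: dict) -> ProcessedTrial:
    return ProcessedTrial(
        envelope=trial["envelope"],
        events=None,
        meta=trial["meta"],
        truth={"weightings": trial["true_weightings"]},
    )


def simulate_stage(config: PipelineConfig):
    gt = make_ground_truth(config.generator)
    trials, meta = generate_cohort(
        config.generator, config.seed, level=config.level, gt=gt
    )
    return gt, trials, meta


def preprocess_stage(config: PipelineConfig, trials) -> list[ProcessedTrial]:
    processed: list[ProcessedTrial] = []
    if config.level == "raw":
        by_participant: dict[int, list] = {}
        for rec in trials:
            by_participant.setdefault(rec.meta.participant, []).append(rec)
        for pid in sorted(by_participant):
            processed.extend(
                preprocess_participant(
                    by_participant[pid],
                    skip_ecg=config.skip_ecg,
                    ecg_min_duration_s=config.ecg_min_duration_s,
                )
            )
    else:
        by_participant = {}
        for tr in trials:
            by_participant.setdefault(tr["meta"].participant, []).append(
                _processed_from_envelope(tr)
            )
        for pid in sorted(by_participant):
            normalized, _, _ = normalize_amplitude(by_participant[pid])
            processed.extend(normalized)
    return processed


def group_datasets(processed: list[ProcessedTrial], n_folds: int) -> dict[str, StrategyDataset]:
    groups: dict[str, list[ProcessedTrial]] = {}
    for tr in processed:
        groups.setdefault(tr.meta.dataset_label, []).append(tr)
    datasets = {}
    for label, trs in sorted(groups.items()):
        if len(trs) < n_folds:
            raise FoldError(
                f"strategy dataset {label!r} has only {len(trs)} trials; "
                f"{n_folds}-fold cross-validation needs at least {n_folds}"
            )
        datasets[label] = build_strategy_dataset(trs, label)
    return datasets


def extract_stage(config: PipelineConfig, datasets: dict[str, StrategyDataset]):
    """Cross-validated curves, model selection, final models, compactness."""
    results = {}
    for label, ds in datasets.items():
        entry = {}
        for kind in ("temporal", "spatial"):
            t0 = time.perf_counter()
            curve = cross_validated_curve(
                ds, kind,
                n_values=np.arange(1, config.n_max + 1),
                n_folds=config.n_folds,
                restarts=config.restarts,
                max_iter=config.max_iter,
                seed=config.seed,
            )
            knee = select_n_knee(curve.n_values, curve.r2_mean)
            try:
                star = select_n_star(curve.n_values, curve.r2_mean)
                n_star = star.n_star
            except SelectionError:
                n_star = None
            model = extract_synergies(
                ds, kind, knee.n_knee,
                restarts=config.restarts, max_iter=config.max_iter,
                seed=config.seed,
            )
            entry[kind] = {
                "curve": curve,
                "n_knee": knee.n_knee,
                "n_star": n_star,
                "r2_at_knee": float(curve.r2_mean[knee.n_knee - 1]),
                "model": model,
            }
            logger.info(
                "%s/%s: n_knee=%d n_star=%s (%.1f s)",
                label, kind, knee.n_knee, n_star, time.perf_counter() - t0,
            )
        entry["compactness"] = compactness_summary(
            entry["temporal"]["n_knee"], entry["spatial"]["n_knee"]
        )
        results[label] = entry
    return results


def match_stage(config: PipelineConfig, extraction_results) -> dict[str, dict]:
    """Match temporal profiles across strategies within each movement x floor
    task."""
    tasks: dict[str, list[tuple[str, np.ndarray]]] = {}
    for label, entry in extraction_results.items():
        movement, floor, strategy = label.split("|")
        task = f"{movement}|{floor}"
        C = entry["temporal"]["model"].trial_independent
        for j in range(C.shape[1]):
            tasks.setdefault(task, []).append((strategy, C[:, j]))
    out = {}
    for task, profiles in sorted(tasks.items()):
        sol = find_min_valid_k(profiles, seed=config.seed)
        agreement = robustness_check(
            profiles, repeats=config.match_repeats, seed=config.seed
        )
        sol.robustness = agreement
        out[task] = {"solution": sol, "agreement": agreement}
    return out


def fwhm_stage(extraction_results) -> dict[str, list]:
    out = {}
    for label, entry in extraction_results.items():
        C = entry["temporal"]["model"].trial_independent
        measures = fwhm_table(C)
        # report chronologically, as synergy tables are printed
        order = np.argsort([m.peak_index for m in measures], kind="stable")
        out[label] = [measures[i] for i in order]
    return out


def stats_stage(config: PipelineConfig, datasets, extraction_results):
    out = {}
    for label, entry in extraction_results.items():
        ds = datasets[label]
        supports_present = {t.meta.support for t in ds.trials}
        if len(supports_present & set(SUPPORTS)) < 2:
            logger.info("%s: fewer than 2 support levels; statistics skipped", label)
            continue
        if len({t.meta.participant for t in ds.trials}) < 2:
            logger.info("%s: single participant; statistics skipped", label)
            continue
        model = entry["temporal"]["model"]
        obs_per_synergy = [
            [(t.meta, model.trial_dependent[ti][syn, :]) for ti, t in enumerate(ds.trials)]
            for syn in range(model.n)
        ]
        results = run_support_analysis(obs_per_synergy, base_alpha=config.alpha)
        # Bonferroni bookkeeping: stage 1 corrects for 2 tests per synergy
        assert all(
            abs(r.alpha_stage1 - config.alpha / (2 * model.n)) < 1e-15 for r in results
        )
        out[label] = results
    return out


def _fit_to_dict(fit):
    return {
        "model": fit.model,
        "reference_support": fit.reference_support,
        "coefficients": {
            name: {
                "estimate": float(fit.params[name]),
                "se": float(fit.bse[name]),
                "t": float(fit.tvalues[name]),
                "p": float(fit.pvalues[name]),
            }
            for name in fit.params.index
        },
        "random_intercept_var": fit.random_intercept_var,
        "residual_var": fit.residual_var,
    }


def summarize(config, extraction_results, matches, widths, stats_results) -> dict:
    table1 = {}
    table2 = {}
    pairs = []
    for label, entry in extraction_results.items():
        table1[label] = {
            "n_temporal_knee": entry["temporal"]["n_knee"],
            "n_temporal_star": entry["temporal"]["n_star"],
            "n_spatial_knee": entry["spatial"]["n_knee"],
            "r2_temporal_knee": entry["temporal"]["r2_at_knee"],
            "r2_spatial_knee": entry["spatial"]["r2_at_knee"],
        }
        table2[label] = dataclasses.asdict(entry["compactness"])
        pairs.append((entry["temporal"]["n_knee"], entry["spatial"]["n_knee"]))
    diff_mean, diff_sd = (
        compare_model_counts(pairs) if len(pairs) >= 2 else (None, None)
    )
    cluster_map = {
        task: {
            "k": m["solution"].k,
            "assignments": m["solution"].assignments,
            "strategies": m["solution"].strategies,
            "singletons": m["solution"].singleton_clusters,
            "chronological_order": m["solution"].order,
            "agreement": m["agreement"],
        }
        for task, m in matches.items()
    }
    fwhm_map = {
        label: [
            {
                "synergy": m.synergy,
                "peak_index": m.peak_index,
                "width": m.width,
                "boundary": m.boundary,
            }
            for m in measures
        ]
        for label, measures in widths.items()
    }
    stats_map = {
        label: [
            {
                "synergy": r.synergy,
                "significant": r.significant,
                "alpha_stage1": r.alpha_stage1,
                "alpha_stage2": r.alpha_stage2,
                "stage1": {ref: _fit_to_dict(f) for ref, f in r.stage1.items()},
                "stage2": {ref: _fit_to_dict(f) for ref, f in r.stage2.items()},
            }
            for r in results
        ]
        for label, results in stats_results.items()
    }
    return {
        "seed": config.seed,
        "model_orders": table1,
        "compactness": table2,
        "synergy_count_difference": {"mean": diff_mean, "sd": diff_sd},
        "cluster_map": cluster_map,
        "fwhm": fwhm_map,
        "support_stats": stats_map,
    }


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the summary dict (also written to the run
    directory along with all artifacts when ``write_artifacts``)."""
    out = Path(config.out_dir)
    if config.write_artifacts:
        out.mkdir(parents=True, exist_ok=True)
        snapshot = dataclasses.asdict(config)
        snapshot["out_dir"] = str(config.out_dir)
        skio.write_json(out / "config.json", snapshot)

    gt, trials, meta = simulate_stage(config)
    processed = preprocess_stage(config, trials)
    datasets = group_datasets(processed, config.n_folds)
    extraction_results = extract_stage(config, datasets)
    matches = match_stage(config, extraction_results)
    widths = fwhm_stage(extraction_results)
    stats_results = stats_stage(config, datasets, extraction_results)
    summary = summarize(config, extraction_results, matches, widths, stats_results)

    if config.write_artifacts:
        (out / "processed").mkdir(exist_ok=True)
        for i, tr in enumerate(processed):
            skio.write_trial_tsv(out / "processed" / f"trial_{i:04d}.tsv", tr)
        meta.to_csv(out / "cohort_metadata.tsv", sep="\t", index=False)
        (out / "models").mkdir(exist_ok=True)
        for label, entry in extraction_results.items():
            safe = label.replace("|", "_")
            for kind in ("temporal", "spatial"):
                skio.write_model_json(
                    out / "models" / f"{safe}_{kind}.json", entry[kind]["model"]
                )
                skio.write_curve_json(
                    out / "models" / f"{safe}_{kind}_curve.json", entry[kind]["curve"]
                )
        skio.write_json(out / "summary.json", summary)
    return summary
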
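"""Extract temporal and spatial synergies, select the model order, and
compare compactness.

For each strategy dataset: fivefold cross-validated R² curves for both
arrangements, the R²-knee and N* orders, final NMF models at the knee, and
the trial-independent / trial-dependent parameter counts.
"""

import numpy as np
from common import EXTRACTION_DIR, PROCESSED_DIR, SEED, pipeline_config

from synergykit import io as skio
from synergykit.extraction import (
    build_strategy_dataset,
    compactness_summary,
    compare_model_counts,
    cross_validated_curve,
    extract_synergies,
    select_n_knee,
    select_n_star,
    SelectionError,
)


def main():
    cfg = pipeline_config()
    trials = [skio.read_trial_tsv(p) for p in skio.iter_trial_paths(PROCESSED_DIR)]
    groups = {}
    for t in trials:
        groups.setdefault(t.meta.dataset_label, []).append(t)

    EXTRACTION_DIR.mkdir(parents=True, exist_ok=True)
    selections = {}
    pairs = []
    for label, trs in sorted(groups.items()):
        ds = build_strategy_dataset(trs, label)
        entry = {}
        for kind in ("temporal", "spatial"):
            curve = cross_validated_curve(
                ds, kind, n_values=np.arange(1, cfg.n_max + 1),
                n_folds=cfg.n_folds, restarts=cfg.restarts,
                max_iter=cfg.max_iter, seed=SEED,
            )
            n_knee = select_n_knee(curve.n_values, curve.r2_mean).n_knee
            try:
                n_star = select_n_star(curve.n_values, curve.r2_mean).n_star
            except SelectionError:
                n_star = None
            model = extract_synergies(
                ds, kind, n_knee, restarts=cfg.restarts,
                max_iter=cfg.max_iter, seed=SEED,
            )
            safe = label.replace("|", "_")
            skio.write_curve_json(EXTRACTION_DIR / f"{safe}_{kind}_curve.json", curve)
            skio.write_model_json(EXTRACTION_DIR / f"{safe}_{kind}.json", model)
            entry[kind] = dict(
                n_knee=n_knee, n_star=n_star,
                r2_at_knee=float(curve.r2_mean[n_knee - 1]),
            )
        comp = compactness_summary(entry["temporal"]["n_knee"], entry["spatial"]["n_knee"])
        entry["compactness"] = comp.__dict__
        selections[label] = entry
        pairs.append((comp.n_temporal, comp.n_spatial))
        print(
            f"{label}: temporal knee {entry['temporal']['n_knee']} "
            f"(R² {entry['temporal']['r2_at_knee']:.3f}), "
            f"spatial knee {entry['spatial']['n_knee']} "
            f"(R² {entry['spatial']['r2_at_knee']:.3f}); "
            f"parameter sums {comp.sum_temporal} vs {comp.sum_spatial}"
        )
    if len(pairs) >= 2:
        mean, sd = compare_model_counts(pairs)
        print(f"spatial - temporal order difference: {mean:.1f} ± {sd:.1f}")
        selections["_count_difference"] = {"mean": mean, "sd": sd}
    skio.write_json(EXTRACTION_DIR / "selections.json", selections)


if __name__ == "__main__":
    main()
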
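"""Simulate the raw-signal cohort.

Generates four participants x 18 sit-to-stand trials (3 repetitions x 3
support levels x 1 floor... the configured task) with known ground-truth
synergies, planted full-support effects (upper-body x1.5, lower-limb x0.6),
ECG-contaminated trunk channels, and event-bearing kinetic traces. Writes
one TSV per trial plus JSON sidecars and the ground truth.
"""

from common import COHORT_DIR, SEED, generator_config

from synergykit import io as skio
from synergykit.synthetic import generate_cohort, make_ground_truth


def main():
    cfg = generator_config()
    gt = make_ground_truth(cfg)
    trials, meta = generate_cohort(cfg, SEED, level="raw", gt=gt)
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    for i, rec in enumerate(trials):
        skio.write_raw_recording(COHORT_DIR / f"trial_{i:04d}.tsv", rec)
    meta.to_csv(COHORT_DIR / "metadata.tsv", sep="\t", index=False)
    skio.write_json(
        COHORT_DIR / "ground_truth.json",
        {
            label: {"peaks": s.peaks, "sigmas": s.sigmas, "weightings": s.weightings}
            for label, s in gt.strategies.items()
        },
    )
    counts = meta.groupby("strategy").size().to_dict()
    print(f"wrote {len(trials)} raw trials to {COHORT_DIR}")
    print(f"trials per strategy: {counts}")


if __name__ == "__main__":
    main()
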
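"""Shared configuration for the numbered analysis scripts.

A desk-scale study: four participants, the non-challenging sit-to-stand task
with two movement strategies (three planted synergies each, one of them
strategy-specific in timing), full raw-signal simulation. Every script reads
the previous script's outputs from ``results/``.
"""

from pathlib import Path

from synergykit.pipeline import PipelineConfig
from synergykit.synthetic import GeneratorConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

COHORT_DIR = RESULTS / "cohort"
PROCESSED_DIR = RESULTS / "processed"
EXTRACTION_DIR = RESULTS / "extraction"
MATCHING_DIR = RESULTS / "matching"
TIMING_DIR = RESULTS / "timing"
STATS_DIR = RESULTS / "stats"

SEED = 42  # two participants per strategy in the demo cohort

TASK = ("sit_to_stand", "non_challenging")
FL = "sit_to_stand|non_challenging|forward_leaning"
VR = "sit_to_stand|non_challenging|vertical_rise"


def generator_config() -> GeneratorConfig:
    return GeneratorConfig(
        participants=4,
        movements=("sit_to_stand",),
        floors=("non_challenging",),
        synergy_counts={FL: 3, VR: 3},
        strategy_profiles={
            # shared early and seat-off synergies; a late synergy that peaks
            # earlier in the vertical-rise strategy
            FL: ([8, 45, 92], [8, 5, 8]),
            VR: ([8, 45, 70], [8, 5, 6]),
        },
        task_strategies={TASK: ["forward_leaning", "vertical_rise"]},
    )


def pipeline_config() -> PipelineConfig:
    return PipelineConfig(
        seed=SEED,
        out_dir=RESULTS / "run",
        generator=generator_config(),
        level="raw",
        n_max=6,
        n_folds=5,
        restarts=3,
        max_iter=500,
        match_repeats=10,
        ecg_min_duration_s=20.0,
    )
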
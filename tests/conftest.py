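import numpy as np
import pytest

from synergykit.datatypes import ProcessedTrial
from synergykit.preprocessing import normalize_amplitude
from synergykit.synthetic import (
    GeneratorConfig,
    NoiseModel,
    generate_cohort,
    make_ground_truth,
)

LABEL = "sit_to_stand|non_challenging|a"


def single_strategy_config(
    peaks=(10, 50, 90),
    sigmas=(6, 5, 6),
    noise=None,
    participants=1,
    weighting_seed=12345,
):
    """One-strategy sit-to-stand configuration used across the tests."""
    n = len(peaks)
    return GeneratorConfig(
        synergy_counts={LABEL: n},
        strategy_profiles={LABEL: (list(peaks), list(sigmas))},
        task_strategies={("sit_to_stand", "non_challenging"): ["a"]},
        movements=("sit_to_stand",),
        floors=("non_challenging",),
        participants=participants,
        noise=noise or NoiseModel(),
        weighting_seed=weighting_seed,
    )


@pytest.fixture(scope="session")
def noiseless_gt():
    cfg = single_strategy_config(noise=NoiseModel(envelope_sd=0.0, jitter_sigma=0.0))
    return make_ground_truth(cfg)


@pytest.fixture(scope="session")
def noisy_envelope_trials():
    """18 normalized envelope-level trials of one participant (default noise)."""
    cfg = single_strategy_config()
    gt = make_ground_truth(cfg)
    trials, _ = generate_cohort(cfg, seed=11, level="envelope", gt=gt)
    pts = [
        ProcessedTrial(
            envelope=t["envelope"], events=None, meta=t["meta"],
            truth={"weightings": t["true_weightings"]},
        )
        for t in trials
    ]
    normalized, _, _ = normalize_amplitude(pts)
    return normalized


def gaussian_bump(peak, sigma, n=101):
    t = np.arange(n, dtype=float)
    b = np.exp(-0.5 * ((t - peak) / sigma) ** 2)
    return b / b.max()
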
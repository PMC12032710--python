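"""Synthetic cohorts with known ground-truth synergies.

The generator is the inverse of the temporal synergy model: each movement
strategy owns a set of trial-independent activation profiles (unit-maximum
truncated Gaussian bumps on the 0-100 % cycle grid) and per-synergy baseline
muscle weightings. A trial's envelope matrix is

    M = sum_n C_n * w_n + noise,  clipped at zero,

where the realized weightings w_n are the baseline weightings scaled by
support-dependent muscle-group factors and trial-level lognormal jitter.
Raw-signal trials additionally modulate band-limited EMG-like carriers with
the envelope, add mains hum and (on trunk channels) periodic ECG-shaped
artifacts, and provide event-bearing ground-reaction-force, seat-force and
CoM traces.

Bumps near the seat transition are narrower than bumps near the movement
boundaries, reproducing the observed timing structure of standing up and
sitting down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .datatypes import (
    EventTimes,
    N_TIME,
    RawTrialRecording,
    Series,
    SUPPORTS,
    TrialMeta,
)
from .muscles import CHANNEL_GROUPS, N_CHANNELS, TRUNK_CHANNEL_INDICES


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


TIME_GRID = np.arange(N_TIME, dtype=float)  # 0..100 % of the cycle

# Strategy labels per movement x floor, as observed in young adults.
TASK_STRATEGIES: dict[tuple[str, str], list[str]] = {
    ("sit_to_stand", "non_challenging"): ["forward_leaning", "hybrid", "vertical_rise"],
    ("sit_to_stand", "challenging"): ["exaggerated_forward_leaning", "forward_leaning"],
    ("stand_to_sit", "non_challenging"): ["vertical_lowering", "hybrid", "backward_lowering"],
    ("stand_to_sit", "challenging"): ["exaggerated_forward_leaning", "forward_leaning"],
}

# Default planted synergy counts per task-strategy (temporal model orders of
# the study conditions).
DEFAULT_SYNERGY_COUNTS: dict[str, int] = {
    "sit_to_stand|non_challenging|forward_leaning": 7,
    "sit_to_stand|non_challenging|hybrid": 6,
    "sit_to_stand|non_challenging|vertical_rise": 6,
    "sit_to_stand|challenging|exaggerated_forward_leaning": 10,
    "sit_to_stand|challenging|forward_leaning": 8,
    "stand_to_sit|non_challenging|vertical_lowering": 8,
    "stand_to_sit|non_challenging|hybrid": 8,
    "stand_to_sit|non_challenging|backward_lowering": 8,
    "stand_to_sit|challenging|exaggerated_forward_leaning": 7,
    "stand_to_sit|challenging|forward_leaning": 7,
}

# FS shifts activity from the legs to the arms; LT is a mild haptic cue.
# The arm increase outweighs the leg decrease, so the stacked response also
# carries a net shift (load transfer adds work for the upper body).
DEFAULT_SUPPORT_EFFECTS: dict[str, dict[str, float]] = {
    "UA": {"upper_body": 1.0, "lower_limb": 1.0, "trunk": 1.0},
    "LT": {"upper_body": 1.15, "lower_limb": 0.95, "trunk": 1.0},
    "FS": {"upper_body": 1.6, "lower_limb": 0.6, "trunk": 1.0},
}


@dataclass
class NoiseModel:
    envelope_sd: float = 0.05       # additive envelope noise, unit-max scale
    jitter_sigma: float = 0.2       # lognormal sigma of trial weighting jitter
    ecg_amplitude: float = 4.0      # ECG peak relative to carrier RMS on trunk
    hum_amplitude: float = 0.05     # 50 Hz mains hum relative to carrier RMS
    heart_rate_hz: float = 1.2
    kinetic_noise: float = 0.005    # kinetic-trace noise, body-weight fraction


@dataclass
class EventSpec:
    """True event times (seconds) shared by all generated recordings."""

    movement_start: float = 1.0
    seat_transition: float = 1.5
    movement_end: float = 2.4
    total_duration: float = 3.2

    def __post_init__(self):
        if not (0.3 <= self.movement_start < self.seat_transition < self.movement_end):
            raise ConfigurationError(
                "event times must satisfy 0.3 <= start < seat < end "
                f"(got {self.movement_start}, {self.seat_transition}, {self.movement_end})"
            )
        if self.total_duration < self.movement_end + 0.3:
            raise ConfigurationError("total_duration must exceed movement_end + 0.3 s")


@dataclass
class StrategySpec:
    """Ground truth for one task-strategy."""

    label: str
    peaks: np.ndarray      # (n,) peak times, % of cycle
    sigmas: np.ndarray     # (n,) Gaussian width parameters, % of cycle
    weightings: np.ndarray  # (n, 30) baseline nonnegative muscle weightings

    @property
    def n_synergies(self) -> int:
        return len(self.peaks)

    def profiles(self) -> np.ndarray:
        """Unit-maximum activation profiles, shape (101, n)."""
        return profile_matrix(self.peaks, self.sigmas)


@dataclass
class GroundTruth:
    strategies: dict[str, StrategySpec]
    support_effects: dict[str, dict[str, float]]
    noise: NoiseModel
    events: EventSpec

    def __post_init__(self):
        for sup, factors in self.support_effects.items():
            for g, f in factors.items():
                if f <= 0:
                    raise ConfigurationError(
                        f"support_effects[{sup}][{g}] must be > 0, got {f}"
                    )
        ua = self.support_effects.get("UA", {})
        if any(abs(v - 1.0) > 1e-12 for v in ua.values()):
            raise ConfigurationError("support_effects['UA'] factors must all be 1")

    def channel_factors(self, support: str) -> np.ndarray:
        """Per-channel multiplicative support factor, shape (30,)."""
        if support not in self.support_effects:
            raise KeyError(f"unknown support level {support!r}")
        factors = self.support_effects[support]
        return np.array([factors[g] for g in CHANNEL_GROUPS])


def profile_matrix(peaks, sigmas) -> np.ndarray:
    """Truncated-Gaussian unit-max bumps on the 101-point grid, (101, n)."""
    peaks = np.atleast_1d(np.asarray(peaks, dtype=float))
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if np.any(sigmas <= 0):
        raise ConfigurationError("profile width parameters (sigmas) must be > 0")
    if np.any((peaks < 0) | (peaks > 100)):
        raise ConfigurationError("profile peak times must lie in [0, 100] % of cycle")
    C = np.exp(-0.5 * ((TIME_GRID[:, None] - peaks[None, :]) / sigmas[None, :]) ** 2)
    return C / C.max(axis=0, keepdims=True)


def default_sigma(peak: float, narrow: float = 4.0, wide: float = 10.0) -> float:
    """Width rule: narrow near the seat transition (mid-cycle), wide at the
    boundaries."""
    return narrow + (wide - narrow) * abs(peak - 50.0) / 50.0


@dataclass
class GeneratorConfig:
    """Settings for :func:`make_ground_truth` and :func:`generate_cohort`."""

    # strategy label -> synergy count, or explicit (peaks, sigmas) via
    # strategy_profiles. Default: the ten task-strategies of the study.
    synergy_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SYNERGY_COUNTS)
    )
    strategy_profiles: dict[str, tuple[list[float], list[float]]] = field(
        default_factory=dict
    )
    support_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SUPPORT_EFFECTS.items()}
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    events: EventSpec = field(default_factory=EventSpec)
    weighting_seed: int = 12345  # baseline weightings are part of the truth

    # cohort layout
    participants: int = 20
    repetitions: int = 3
    movements: tuple[str, ...] = ("sit_to_stand", "stand_to_sit")
    floors: tuple[str, ...] = ("non_challenging", "challenging")
    supports: tuple[str, ...] = SUPPORTS
    # 'fixed': one strategy per participant x floor x movement; 'probabilistic':
    # re-drawn per trial.
    strategy_rule: str = "fixed"
    task_strategies: dict[tuple[str, str], list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in TASK_STRATEGIES.items()}
    )


def make_ground_truth(config: GeneratorConfig | None = None) -> GroundTruth:
    """Construct a fully specified :class:`GroundTruth` from generator settings.

    Peaks default to an even spread over the cycle; widths follow the
    narrow-at-seat-transition rule. Baseline weightings are drawn once from a
    seeded gamma distribution and scaled to unit maximum per synergy.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.weighting_seed)
    strategies: dict[str, StrategySpec] = {}
    for label, n in config.synergy_counts.items():
        if not (1 <= n <= 30):
            raise ConfigurationError(
                f"synergy_counts[{label!r}] must be in [1, 30], got {n}"
            )
        if label in config.strategy_profiles:
            peaks, sigmas = config.strategy_profiles[label]
            peaks = np.asarray(peaks, dtype=float)
            sigmas = np.asarray(sigmas, dtype=float)
            if len(peaks) != n or len(sigmas) != n:
                raise ConfigurationError(
                    f"strategy_profiles[{label!r}] must list {n} peaks and widths"
                )
        else:
            peaks = np.linspace(2.0, 98.0, n)
            sigmas = np.array([default_sigma(p) for p in peaks])
        if np.any(sigmas <= 0):
            raise ConfigurationError(
                f"strategy_profiles[{label!r}]: widths must be positive"
            )
        # gamma(2) weights: nonnegative, heavy enough tail for muscle dominance.
        # Sparsity makes the planted factorization separable (identifiable):
        # each synergy keeps two private channels no other synergy loads, and
        # a fraction of the remaining weights is zeroed.
        w = rng.gamma(shape=2.0, scale=0.5, size=(n, N_CHANNELS))
        w *= rng.random((n, N_CHANNELS)) > 0.25
        # group-dominant structure: mid-cycle (seat-transition) synergies are
        # lower-limb dominant (leg extension), boundary synergies upper-body /
        # trunk dominant (stabilization and arm use)
        upper = np.array([g == "upper_body" for g in CHANNEL_GROUPS])
        lower = np.array([g == "lower_limb" for g in CHANNEL_GROUPS])
        trunk = np.array([g == "trunk" for g in CHANNEL_GROUPS])
        for i, p in enumerate(peaks):
            if 30.0 <= p <= 70.0:
                w[i, lower] *= 4.0
            else:
                w[i, upper] *= 4.0
                w[i, trunk] *= 2.0
        private = rng.choice(N_CHANNELS, size=(n, 2), replace=(2 * n > N_CHANNELS))
        for i in range(n):
            others = [j for j in range(n) if j != i]
            if others:
                w[np.ix_(others, private[i])] = 0.0
            w[i, private[i]] = np.maximum(w[i, private[i]], 0.5)
        w /= w.max(axis=1, keepdims=True)
        strategies[label] = StrategySpec(label, peaks, sigmas, w)
    for label in config.strategy_profiles:
        if label not in config.synergy_counts:
            raise ConfigurationError(
                f"strategy_profiles names unknown strategy {label!r}"
            )
    return GroundTruth(
        strategies=strategies,
        support_effects={k: dict(v) for k, v in config.support_effects.items()},
        noise=config.noise,
        events=config.events,
    )


def generate_envelope_trial(
    gt: GroundTruth, strategy: str, support: str, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One 101 x 30 nonnegative envelope matrix plus its realized weightings.

    Returns ``(envelope, true_weightings)`` with ``true_weightings`` of shape
    (n_synergies, 30): baseline x support factors x lognormal jitter.
    """
    if strategy not in gt.strategies:
        raise KeyError(f"unknown strategy {strategy!r}")
    spec = gt.strategies[strategy]
    factors = gt.channel_factors(support)
    rng = np.random.default_rng(seed)
    sig = gt.noise.jitter_sigma
    if sig > 0:
        # mean-one lognormal so planted support ratios survive averaging
        jitter = rng.lognormal(mean=-0.5 * sig**2, sigma=sig, size=spec.weightings.shape)
    else:
        jitter = np.ones_like(spec.weightings)
    w = spec.weightings * factors[None, :] * jitter
    env = spec.profiles() @ w
    if gt.noise.envelope_sd > 0:
        env = env + rng.normal(0.0, gt.noise.envelope_sd, size=env.shape)
    return np.clip(env, 0.0, None), w


def _bandlimited_carrier(rng, n, rate, lo=20.0, hi=450.0) -> np.ndarray:
    """Zero-mean unit-RMS band-limited noise carrier."""
    x = rng.standard_normal(n)
    hi = min(hi, 0.45 * rate)
    sos = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = sosfiltfilt(sos, x)
    return y / max(np.std(y), 1e-12)


def _ecg_waveform(rate: float, half_width_s: float = 0.06) -> np.ndarray:
    """QRS-like biphasic pulse (Ricker wavelet), unit peak."""
    t = np.arange(-half_width_s, half_width_s + 1.0 / rate, 1.0 / rate)
    a = 0.012  # 12 ms characteristic width
    w = (1.0 - (t / a) ** 2) * np.exp(-(t**2) / (2 * a**2))
    return w / np.abs(w).max()


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _com_trajectory(t, start, end, h0, h1, tau=0.03):
    """Trapezoidal-velocity vertical CoM path from h0 to h1 over [start, end]."""
    from scipy.special import expit

    v = expit((t - start) / tau) - expit((t - end) / tau)
    pos = np.cumsum(v) * (t[1] - t[0])
    pos = pos - pos[0]
    scale = (h1 - h0) / max(pos[-1], 1e-12)
    return h0 + pos * scale


EMG_RATE_GROUPS = (1500.0, 4000.0)  # two acquisition systems


def generate_raw_recording(
    gt: GroundTruth,
    strategy: str,
    support: str,
    seed: int,
    *,
    movement: str = "sit_to_stand",
    floor: str = "non_challenging",
    participant: int = 1,
    repetition: int = 1,
    body_weight_n: float = 660.0,
    meta_strategy: str | None = None,
) -> RawTrialRecording:
    """One raw-signal trial: EMG carriers modulated by the envelope, mains hum,
    trunk ECG artifacts, and event-bearing GRF / seat-force / CoM traces."""
    ev = gt.events
    rng = np.random.default_rng(seed)
    env_seed = int(rng.integers(2**31))
    envelope, true_w = generate_envelope_trial(gt, strategy, support, env_seed)

    duration = ev.total_duration
    window_start = ev.movement_start - 0.2
    window_end = ev.movement_end
    heart_phase = rng.uniform(0.0, 1.0 / gt.noise.heart_rate_hz)

    emg: list[Series] = []
    baseline_tone = 0.08  # resting muscle tone, unit-max envelope scale
    for ch in range(N_CHANNELS):
        rate = EMG_RATE_GROUPS[0] if ch < 16 else EMG_RATE_GROUPS[1]
        n = int(round(duration * rate))
        t = np.arange(n) / rate
        carrier = _bandlimited_carrier(rng, n, rate)
        # map the 101-point envelope onto wall-clock time inside the window
        phase = np.clip((t - window_start) / (window_end - window_start), 0.0, 1.0)
        mod = np.interp(phase * 100.0, TIME_GRID, envelope[:, ch])
        inside = (t >= window_start) & (t <= window_end)
        amp = baseline_tone + np.where(inside, mod, 0.0)
        x = carrier * amp
        if gt.noise.hum_amplitude > 0:
            x = x + gt.noise.hum_amplitude * np.sin(2 * np.pi * 50.0 * t)
        if gt.noise.ecg_amplitude > 0 and ch in TRUNK_CHANNEL_INDICES:
            wave = _ecg_waveform(rate)
            half = len(wave) // 2
            period = 1.0 / gt.noise.heart_rate_hz
            beat = heart_phase
            while beat < duration:
                i = int(round(beat * rate))
                lo, hi = i - half, i - half + len(wave)
                if lo >= 0 and hi <= n:
                    x[lo:hi] += gt.noise.ecg_amplitude * wave
                beat += period
        emg.append(Series(x, rate))

    # kinetic / kinematic traces with their native rates
    def _kinetics(rate):
        n = int(round(duration * rate))
        return np.arange(n) / rate

    W = body_weight_n
    seat_share = 0.65
    ramp = 0.3
    t_grf = _kinetics(1000.0)
    t_seat = _kinetics(142.0)
    t_com = _kinetics(150.0)

    if movement == "sit_to_stand":
        seat_f = seat_share * W * _smoothstep((ev.seat_transition - t_seat) / ramp)
        com = _com_trajectory(t_com, ev.movement_start, ev.movement_end, 0.55, 0.95)
        seat_on_grf_grid = seat_share * W * _smoothstep((ev.seat_transition - t_grf) / ramp)
    else:
        seat_f = seat_share * W * _smoothstep((t_seat - ev.seat_transition) / ramp)
        com = _com_trajectory(t_com, ev.movement_start, ev.movement_end, 0.95, 0.55)
        seat_on_grf_grid = seat_share * W * _smoothstep((t_grf - ev.seat_transition) / ramp)

    grf = W - seat_on_grf_grid
    # inertial transient around the seat transition
    grf = grf + 0.08 * W * np.exp(-0.5 * ((t_grf - ev.seat_transition) / 0.12) ** 2)
    kn = gt.noise.kinetic_noise * W
    if kn > 0:
        grf = grf + rng.normal(0, kn, size=grf.shape)
        seat_f = seat_f + rng.normal(0, kn, size=seat_f.shape)
        com = com + rng.normal(0, gt.noise.kinetic_noise * 0.05, size=com.shape)

    meta = TrialMeta(
        participant=participant,
        movement=movement,
        floor=floor,
        support=support,
        repetition=repetition,
        strategy=meta_strategy if meta_strategy is not None else strategy,
    )
    truth = {
        "events": EventTimes(ev.movement_start, ev.seat_transition, ev.movement_end),
        "weightings": true_w,
        "envelope": envelope,
    }
    return RawTrialRecording(
        emg=emg,
        grf_vertical=Series(grf, 1000.0),
        seat_force=Series(seat_f, 142.0),
        com_vertical=Series(com, 150.0),
        meta=meta,
        truth=truth,
    )


def generate_cohort(
    config: GeneratorConfig,
    seed: int,
    *,
    level: str = "raw",
    gt: GroundTruth | None = None,
):
    """Generate a full cohort of trials plus a metadata table.

    Per participant and movement: repetitions x supports x floors trials
    (3 x 3 x 2 = 18 by default). ``level='raw'`` yields
    :class:`RawTrialRecording` objects, ``level='envelope'`` yields
    101 x 30 envelope matrices wrapped as dicts with true weightings.

    Randomness: one master generator seeded with ``seed`` draws a child seed
    per trial in a fixed (participant, floor, movement, repetition, support)
    order, so cohorts are reproducible and trials independent.
    """
    if level not in ("raw", "envelope"):
        raise ConfigurationError("level must be 'raw' or 'envelope'")
    if config.strategy_rule not in ("fixed", "probabilistic"):
        raise ConfigurationError("strategy_rule must be 'fixed' or 'probabilistic'")
    gt = gt or make_ground_truth(config)
    master = np.random.default_rng(seed)

    trials = []
    rows = []
    for p in range(1, config.participants + 1):
        for floor in config.floors:
            for movement in config.movements:
                options = config.task_strategies[(movement, floor)]
                fixed_choice = options[int(master.integers(len(options)))]
                for rep in range(1, config.repetitions + 1):
                    for support in config.supports:
                        if config.strategy_rule == "probabilistic":
                            strat = options[int(master.integers(len(options)))]
                        else:
                            strat = fixed_choice
                        child = int(master.integers(2**31))
                        label = f"{movement}|{floor}|{strat}"
                        if level == "raw":
                            trial = generate_raw_recording(
                                gt, label, support, child,
                                movement=movement, floor=floor,
                                participant=p, repetition=rep,
                                meta_strategy=strat,
                            )
                        else:
                            env, w = generate_envelope_trial(gt, label, support, child)
                            trial = {
                                "envelope": env,
                                "true_weightings": w,
                                "meta": TrialMeta(p, movement, floor, support, rep, strat),
                            }
                        trials.append(trial)
                        rows.append(
                            dict(
                                participant=p, movement=movement, floor=floor,
                                support=support, repetition=rep, strategy=strat,
                                seed=child,
                            )
                        )
    return trials, pd.DataFrame(rows)
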
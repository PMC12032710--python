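"""Raw EMG to 101 x 30 amplitude-normalized envelopes.

The chain: band-pass (20-500 Hz) + 50 Hz notch, zero-lag; template-based ECG
artifact subtraction on trunk channels; full-wave rectification and 10 Hz
zero-lag low-pass; movement-event detection by 3-phase k-means++ on
standardized kinetic/kinematic features; segmentation from 200 ms before
movement start to movement end; cubic-spline resampling to 101 points; and
per-muscle, per-participant amplitude normalization to the maximum across
that participant's trials.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, iirnotch, filtfilt, sosfiltfilt
from sklearn.cluster import KMeans

from .datatypes import (
    EventTimes,
    N_TIME,
    PRE_WINDOW_S,
    ProcessedTrial,
    RawTrialRecording,
    Series,
)
from .muscles import N_CHANNELS, TRUNK_CHANNEL_INDICES

logger = logging.getLogger(__name__)


class SamplingRateError(ValueError):
    pass


class TemplateFailureError(RuntimeError):
    """ECG template could not be built (too few beats / too little data)."""


class DetectionError(RuntimeError):
    """Movement events could not be identified."""


class SegmentationError(ValueError):
    pass


def bandpass_notch_filter(signal: np.ndarray, rate: float) -> np.ndarray:
    """4th-order zero-lag Butterworth band-pass 20-500 Hz plus 50 Hz notch."""
    if rate <= 1000.0:
        raise SamplingRateError(
            f"sampling rate must exceed 1000 Hz for a 500 Hz band edge, got {rate}"
        )
    signal = np.asarray(signal, dtype=float)
    # the narrow notch (Q=30) rings for ~0.2 s: pad with the whole signal so
    # edge transients die out and forward-backward filtering stays symmetric
    pad = len(signal) - 1
    sos = butter(4, [20.0, 500.0], btype="bandpass", fs=rate, output="sos")
    out = sosfiltfilt(sos, signal, padlen=pad)
    b, a = iirnotch(50.0, Q=30.0, fs=rate)
    return filtfilt(b, a, out, padlen=pad)


def _smoothed_abs(signal: np.ndarray, rate: float, win_s: float = 0.05) -> np.ndarray:
    win = max(int(round(win_s * rate)), 1)
    kernel = np.ones(win) / win
    return np.convolve(np.abs(signal), kernel, mode="same")


def build_ecg_template(
    trunk_signals: list[np.ndarray],
    rate: float,
    *,
    min_duration_s: float = 30.0,
    refractory_s: float = 0.3,
    half_window_s: float = 0.06,
    threshold_sigmas: float = 3.5,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Detect QRS-like events and build a mean beat-aligned artifact template.

    Signals are processed jointly: beats are picked per signal on a smoothed
    absolute trace (robust threshold, refractory period), the template is the
    mean over all beat-aligned windows. Returns ``(template, beat_indices)``
    with one index array per input signal.
    """
    total = sum(len(s) for s in trunk_signals) / rate
    if total < min_duration_s:
        raise TemplateFailureError(
            f"need >= {min_duration_s} s of signal for a stable template, got {total:.1f} s"
        )
    half = int(round(half_window_s * rate))
    windows = []
    beats_per_signal: list[np.ndarray] = []
    for sig in trunk_signals:
        sig = np.asarray(sig, dtype=float)
        smooth = _smoothed_abs(sig, rate)
        med = np.median(smooth)
        mad = np.median(np.abs(smooth - med))
        height = med + threshold_sigmas * 1.4826 * mad
        peaks, _ = find_peaks(
            smooth, height=height, distance=max(int(refractory_s * rate), 1)
        )
        beats_per_signal.append(peaks)
        for p in peaks:
            if p - half >= 0 and p + half + 1 <= len(sig):
                windows.append(sig[p - half : p + half + 1])
    if len(windows) < 10:
        raise TemplateFailureError(
            f"only {len(windows)} beats detected; need >= 10 for a template"
        )
    template = np.mean(windows, axis=0)
    return template, beats_per_signal


def remove_ecg_artifacts(
    signal: np.ndarray, template: np.ndarray, beat_indices: np.ndarray
) -> np.ndarray:
    """Subtract the template at each beat, scaled by a per-beat least-squares
    fit to the local window. Samples outside beat windows are untouched."""
    out = np.asarray(signal, dtype=float).copy()
    template = np.asarray(template, dtype=float)
    denom = float(template @ template)
    if denom == 0.0 or len(beat_indices) == 0:
        return out
    half = len(template) // 2
    for b in np.asarray(beat_indices, dtype=int):
        lo = b - half
        hi = lo + len(template)
        if lo < 0 or hi > len(out):
            logger.debug("skipping beat at %d: window exceeds signal edge", b)
            continue
        scale = float(out[lo:hi] @ template) / denom
        out[lo:hi] -= scale * template
    return out


def rectify_and_smooth(signal: np.ndarray, rate: float) -> np.ndarray:
    """Full-wave rectification, 4th-order zero-lag 10 Hz low-pass, clip at 0."""
    if rate <= 20.0:
        raise SamplingRateError(f"rate must exceed 20 Hz, got {rate}")
    x = np.abs(np.asarray(signal, dtype=float))
    sos = butter(4, 10.0, btype="lowpass", fs=rate, output="sos")
    env = sosfiltfilt(sos, x, padlen=min(len(x) - 1, int(rate)))
    return np.clip(env, 0.0, None)


def lowpass_10hz(signal: np.ndarray, rate: float) -> np.ndarray:
    """Force/kinematic conditioning: 4th-order zero-lag 10 Hz Butterworth."""
    x = np.asarray(signal, dtype=float)
    sos = butter(4, 10.0, btype="lowpass", fs=rate, output="sos")
    return sosfiltfilt(sos, x, padlen=min(len(x) - 1, int(rate)))


def _mode_smooth(labels: np.ndarray, win: int = 15) -> np.ndarray:
    """Sliding-mode smoothing of a categorical label sequence."""
    half = win // 2
    out = labels.copy()
    for i in range(len(labels)):
        lo = max(0, i - half)
        hi = min(len(labels), i + half + 1)
        vals, counts = np.unique(labels[lo:hi], return_counts=True)
        out[i] = vals[np.argmax(counts)]
    return out


def detect_events(
    grf_vertical: Series,
    seat_force: Series,
    com_vertical: Series,
    movement: str,
    *,
    grid_rate: float = 100.0,
    seat_threshold_frac: float = 0.02,
    velocity_weight: float = 2.0,
    random_state: int = 0,
) -> EventTimes:
    """Identify movement start, seat transition, and movement end.

    Standardized features (vertical GRF, seat force, CoM height, CoM vertical
    velocity) on a common grid are clustered into 3 phases with k-means++;
    the contiguous middle phase bounds the movement, and the seat transition
    is where the seat force crosses a near-zero threshold (2 % of the sitting
    seat load by default) within that phase.
    """
    t_end = min(s.duration for s in (grf_vertical, seat_force, com_vertical))
    t = np.arange(0.0, t_end - 1.0 / grid_rate, 1.0 / grid_rate)

    def prep(series: Series) -> np.ndarray:
        filt = lowpass_10hz(series.values, series.rate)
        return np.interp(t, series.times, filt)

    grf = prep(grf_vertical)
    seat = prep(seat_force)
    com = prep(com_vertical)
    vel = np.gradient(com, t)

    feats = np.column_stack([grf, seat, com, vel])
    sd = feats.std(axis=0)
    if np.any(sd < 1e-9) or vel.std() < 1e-9:
        raise DetectionError("signals show no transition (constant features)")
    feats = (feats - feats.mean(axis=0)) / sd
    # CoM velocity separates the moving phase from both static phases;
    # up-weighting it sharpens the phase boundaries
    feats[:, 3] *= velocity_weight

    km = KMeans(n_clusters=3, init="k-means++", n_init=10, random_state=random_state)
    labels = km.fit_predict(feats)
    labels = _mode_smooth(labels, win=15)
    if len(np.unique(labels)) < 3:
        raise DetectionError(
            "fewer than 3 distinct phases after smoothing; "
            f"label counts: {np.bincount(labels).tolist()}"
        )
    l0, l1 = labels[0], labels[-1]
    if l0 == l1:
        middle = labels != l0
    else:
        middle = (labels != l0) & (labels != l1)
    if not middle.any():
        raise DetectionError("no middle phase found between boundary phases")
    # largest contiguous run of the middle phase
    idx = np.flatnonzero(middle)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    run = max(splits, key=len)
    start, end = t[run[0]], t[run[-1]]

    sitting_load = float(np.percentile(seat, 95))
    thr = seat_threshold_frac * sitting_load
    inside = (t >= start) & (t <= end)
    if movement == "sit_to_stand":
        crossing = inside & (seat < thr)
    else:
        crossing = inside & (seat > thr)
    if not crossing.any():
        raise DetectionError("seat force never crosses the transition threshold")
    seat_time = float(t[np.flatnonzero(crossing)[0]])
    seat_time = min(max(seat_time, start + 1e-6), end - 1e-6)
    return EventTimes(float(start), seat_time, float(end))


def segment_and_normalize_time(
    channel_envelopes: list[Series], events: EventTimes
) -> np.ndarray:
    """Cut [start - 0.2 s, end] and spline-resample each channel to 101 points."""
    if len(channel_envelopes) != N_CHANNELS:
        raise SegmentationError(
            f"expected {N_CHANNELS} channels, got {len(channel_envelopes)}"
        )
    w0 = events.movement_start - events.pre_window
    w1 = events.movement_end
    out = np.empty((N_TIME, N_CHANNELS))
    grid = np.linspace(w0, w1, N_TIME)
    for ch, series in enumerate(channel_envelopes):
        if w0 < -1e-9 or w1 > series.duration + 1e-9:
            raise SegmentationError(
                f"window [{w0:.3f}, {w1:.3f}] s exceeds channel {ch} recording "
                f"span [0, {series.duration:.3f}] s"
            )
        spline = CubicSpline(series.times, series.values)
        out[:, ch] = spline(grid)
    return np.clip(out, 0.0, None)


def normalize_amplitude(
    trials: list[ProcessedTrial],
) -> tuple[list[ProcessedTrial], np.ndarray, np.ndarray]:
    """Divide each muscle by its maximum across one participant's trials.

    Returns (normalized trials, factors[30], flagged[30]); an identically-zero
    muscle is left unscaled with its factor flagged.
    """
    if not trials:
        raise ValueError("need at least one trial")
    stack = np.stack([tr.envelope for tr in trials])
    factors = stack.max(axis=(0, 1))
    flagged = factors <= 0.0
    safe = np.where(flagged, 1.0, factors)
    normalized = [
        ProcessedTrial(
            envelope=tr.envelope / safe,
            events=tr.events,
            meta=tr.meta,
            normalization_factors=safe.copy(),
            truth=tr.truth,
        )
        for tr in trials
    ]
    return normalized, safe, flagged


def preprocess_participant(
    recordings: list[RawTrialRecording],
    *,
    skip_ecg: bool = False,
    ecg_min_duration_s: float = 30.0,
    drop_corrupt: bool = True,
) -> list[ProcessedTrial]:
    """Full chain for all trials of one participant.

    The ECG template is muscle- and participant-specific: for each trunk
    channel it is built jointly from that channel's filtered signal across all
    of the participant's trials. Trials flagged with corrupt channels are
    dropped (exclusion policy), and amplitude normalization runs across the
    participant's remaining trials.
    """
    kept = [r for r in recordings if not (drop_corrupt and r.corrupt_channels)]
    if not kept:
        raise ValueError("all trials excluded as corrupt")

    filtered: list[list[np.ndarray]] = []
    for rec in kept:
        filtered.append(
            [bandpass_notch_filter(s.values, s.rate) for s in rec.emg]
        )

    if not skip_ecg:
        for ch in TRUNK_CHANNEL_INDICES:
            rate = kept[0].emg[ch].rate
            signals = [f[ch] for f in filtered]
            try:
                template, beats = build_ecg_template(
                    signals, rate, min_duration_s=ecg_min_duration_s
                )
            except TemplateFailureError as exc:
                warnings.warn(f"ECG removal skipped for channel {ch}: {exc}")
                continue
            for f, b in zip(filtered, beats):
                f[ch] = remove_ecg_artifacts(f[ch], template, b)

    processed: list[ProcessedTrial] = []
    for rec, chans in zip(kept, filtered):
        envelopes = [
            Series(rectify_and_smooth(x, s.rate), s.rate)
            for x, s in zip(chans, rec.emg)
        ]
        events = detect_events(
            rec.grf_vertical, rec.seat_force, rec.com_vertical, rec.meta.movement
        )
        matrix = segment_and_normalize_time(envelopes, events)
        processed.append(
            ProcessedTrial(envelope=matrix, events=events, meta=rec.meta, truth=rec.truth)
        )
    normalized, _, _ = normalize_amplitude(processed)
    return normalized
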
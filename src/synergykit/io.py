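"""Plain-text artifact formats: TSV matrices and JSON sidecars.

Every stage reads and writes inspectable text: envelope matrices as 101 x 30
TSV tables with muscle-code headers, raw recordings as padded TSV with
per-channel rates in the JSON sidecar, models/curves/solutions as JSON with
full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EventTimes, ProcessedTrial, RawTrialRecording, Series, TrialMeta
from .extraction import CrossValidationCurve, SynergyModel
from .muscles import CHANNEL_NAMES


class FormatError(ValueError):
    pass


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else str(k)): _to_jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_json(path: Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(payload), indent=1))


def read_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())


def write_trial_tsv(path: Path, trial: ProcessedTrial) -> None:
    """Envelope as TSV (101 rows, 30 labeled columns) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(trial.envelope, columns=CHANNEL_NAMES)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "meta": trial.meta.to_dict(),
        "events": trial.events.to_dict() if trial.events else None,
        "normalization_factors": trial.normalization_factors,
    }
    write_json(path.with_suffix(".json"), sidecar)


def read_trial_tsv(path: Path) -> ProcessedTrial:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != CHANNEL_NAMES:
        raise FormatError(
            f"{path}: header does not match the documented 30-muscle order"
        )
    sidecar = read_json(path.with_suffix(".json"))
    events = EventTimes(**sidecar["events"]) if sidecar.get("events") else None
    factors = sidecar.get("normalization_factors")
    return ProcessedTrial(
        envelope=df.to_numpy(),
        events=events,
        meta=TrialMeta(**sidecar["meta"]),
        normalization_factors=np.asarray(factors) if factors is not None else None,
    )


def write_raw_recording(path: Path, rec: RawTrialRecording) -> None:
    """Raw trial as one NaN-padded TSV (columns = EMG channels + kinetics)
    plus a JSON sidecar with per-channel rates, metadata and any truth."""
    path = Path(path)
    columns = {name: s.values for name, s in zip(CHANNEL_NAMES, rec.emg)}
    columns["GRF_V"] = rec.grf_vertical.values
    columns["SEAT_F"] = rec.seat_force.values
    columns["COM_V"] = rec.com_vertical.values
    n = max(len(v) for v in columns.values())
    padded = {
        k: np.concatenate([v, np.full(n - len(v), np.nan)]) for k, v in columns.items()
    }
    pd.DataFrame(padded).to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "meta": rec.meta.to_dict(),
        "rates": {name: s.rate for name, s in zip(CHANNEL_NAMES, rec.emg)},
        "kinetic_rates": {
            "GRF_V": rec.grf_vertical.rate,
            "SEAT_F": rec.seat_force.rate,
            "COM_V": rec.com_vertical.rate,
        },
        "corrupt_channels": list(rec.corrupt_channels),
        "truth": {
            "events": rec.truth["events"].to_dict(),
            "weightings": rec.truth["weightings"],
        }
        if rec.truth
        else None,
    }
    write_json(path.with_suffix(".json"), sidecar)


def read_raw_recording(path: Path) -> RawTrialRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    expected = CHANNEL_NAMES + ["GRF_V", "SEAT_F", "COM_V"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: unexpected raw-recording header")
    sidecar = read_json(path.with_suffix(".json"))
    rates = sidecar["rates"]
    krates = sidecar["kinetic_rates"]

    def col(name, rate):
        v = df[name].to_numpy()
        return Series(v[~np.isnan(v)], rate)

    truth = None
    if sidecar.get("truth"):
        truth = {
            "events": EventTimes(**sidecar["truth"]["events"]),
            "weightings": np.asarray(sidecar["truth"]["weightings"]),
        }
    return RawTrialRecording(
        emg=[col(name, rates[name]) for name in CHANNEL_NAMES],
        grf_vertical=col("GRF_V", krates["GRF_V"]),
        seat_force=col("SEAT_F", krates["SEAT_F"]),
        com_vertical=col("COM_V", krates["COM_V"]),
        meta=TrialMeta(**sidecar["meta"]),
        truth=truth,
        corrupt_channels=tuple(sidecar.get("corrupt_channels", ())),
    )


def write_model_json(path: Path, model: SynergyModel) -> None:
    write_json(
        path,
        {
            "kind": model.kind,
            "n": model.n,
            "trial_independent": model.trial_independent,
            "trial_dependent": [w for w in model.trial_dependent],
            "r2_train": model.r2_train,
            "objective": model.objective,
        },
    )


def read_model_json(path: Path) -> SynergyModel:
    d = read_json(path)
    return SynergyModel(
        kind=d["kind"],
        n=int(d["n"]),
        trial_independent=np.asarray(d["trial_independent"]),
        trial_dependent=[np.asarray(w) for w in d["trial_dependent"]],
        r2_train=float(d["r2_train"]),
        objective=float(d["objective"]),
    )


def write_curve_json(path: Path, curve: CrossValidationCurve) -> None:
    write_json(
        path,
        {
            "kind": curve.kind,
            "n_values": curve.n_values,
            "r2_cv": curve.r2_cv,
        },
    )


def read_curve_json(path: Path) -> CrossValidationCurve:
    d = read_json(path)
    return CrossValidationCurve(
        kind=d["kind"],
        n_values=np.asarray(d["n_values"], dtype=int),
        r2_cv=np.asarray(d["r2_cv"]),
    )


def iter_trial_paths(directory: Path, pattern: str = "trial_*.tsv"):
    """Sorted trial TSV paths; reading is per-file, so large cohorts never
    have to live in memory at once."""
    return sorted(Path(directory).glob(pattern))
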
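"""Preprocess raw recordings into normalized 101 x 30 envelope trials.

Band-pass + notch filtering, per-participant ECG template subtraction on the
trunk channels, rectification and smoothing, k-means phase detection of
movement start / seat-off / movement end, segmentation (with the 200 ms
pre-window) to 101 points, and per-muscle, per-participant amplitude
normalization.
"""

import warnings

import numpy as np
from common import COHORT_DIR, PROCESSED_DIR

from synergykit import io as skio
from synergykit.preprocessing import preprocess_participant


def main():
    recs = [skio.read_raw_recording(p) for p in skio.iter_trial_paths(COHORT_DIR)]
    by_p = {}
    for r in recs:
        by_p.setdefault(r.meta.participant, []).append(r)
    PROCESSED_DIR.mkdir(parents=True, exist_ok=True)
    i = 0
    event_errors = []
    for pid in sorted(by_p):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            processed = preprocess_participant(by_p[pid], ecg_min_duration_s=20.0)
        for tr, raw in zip(processed, by_p[pid]):
            if raw.truth is not None:
                true_ev = raw.truth["events"]
                event_errors.append(
                    [
                        abs(tr.events.movement_start - true_ev.movement_start),
                        abs(tr.events.seat_transition - true_ev.seat_transition),
                        abs(tr.events.movement_end - true_ev.movement_end),
                    ]
                )
            skio.write_trial_tsv(PROCESSED_DIR / f"trial_{i:04d}.tsv", tr)
            i += 1
    err = np.array(event_errors)
    print(f"wrote {i} processed trials to {PROCESSED_DIR}")
    print(
        "median |event error| (s): start %.3f, seat transition %.3f, end %.3f"
        % tuple(np.median(err, axis=0))
    )


if __name__ == "__main__":
    main()
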
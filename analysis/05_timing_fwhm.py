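"""Activation duration of every temporal synergy (FWHM, % of cycle).

Profiles are reported chronologically per strategy; boundary synergies are
measured one-sided from the movement start or to the movement end.
"""

import numpy as np
from common import EXTRACTION_DIR, TASK, TIMING_DIR

from synergykit import io as skio
from synergykit.timing import fwhm_table


def main():
    movement, floor = TASK
    prefix = f"{movement}_{floor}_"
    TIMING_DIR.mkdir(parents=True, exist_ok=True)
    lines = ["strategy\tsynergy\tpeak_pct\twidth_pct\tboundary"]
    for p in sorted(EXTRACTION_DIR.glob(f"{prefix}*_temporal.json")):
        strategy = p.stem[len(prefix):-len("_temporal")]
        model = skio.read_model_json(p)
        measures = fwhm_table(model.trial_independent)
        order = np.argsort([m.peak_index for m in measures], kind="stable")
        for rank, i in enumerate(order, start=1):
            m = measures[i]
            lines.append(
                f"{strategy}\t{rank}\t{m.peak_index}\t{m.width:.1f}\t{m.boundary}"
            )
            print(
                f"{strategy} synergy {rank}: peak {m.peak_index} %, "
                f"width {m.width:.1f} % ({m.boundary})"
            )
    (TIMING_DIR / "fwhm.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
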
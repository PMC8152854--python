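#!/usr/bin/env python
"""Benchmark the discharge detector and onset classifier on planted events.

Finding (seed 2024): recall and precision 1.0 on 30 planted discharges,
onset-class agreement > 0.9, LVF attenuation recovered to a few percent;
all 8-s bursts rejected by the >= 10 s duration rule.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from kindleictal import benchmarks as bench

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    det = bench.detection_bench(n_events=30, seed=SEED)
    short = bench.short_burst_bench(n_bursts=10, seed=SEED)
    rows = {
        "n_planted": det["n_planted"],
        "recall": det["recall"],
        "precision": det["precision"],
        "onset_class_agreement": det["class_agreement"],
        "median_abs_onset_error_s": float(np.median(np.abs(det["onset_errors_s"]))),
        "median_abs_duration_error_s": float(np.median(np.abs(det["duration_errors_s"]))),
        "lvf_attenuation_median_abs_rel_err": float(
            np.median(np.abs(det["lvf_rel_errors"]))
        ),
        "short_bursts_planted": short["n_bursts"],
        "short_bursts_detected": short["n_detected"],
    }
    out = pd.DataFrame([rows])
    out.to_csv(RESULTS / "02_detection_bench.csv", index=False)
    print(out.T.to_string(header=False))
    print("\nall planted sub-10 s bursts rejected"
          if short["n_detected"] == 0 else "\nWARNING: short bursts leaked through")


if __name__ == "__main__":
    main()
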
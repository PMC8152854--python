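#!/usr/bin/env python
"""Recover planted cross-frequency coupling with the comodulogram.

Finding (seed 2024): the window-averaged comodulogram peaks within one
log-grid step of the planted (8 Hz phase, 80 Hz amplitude) pair, and MI at
the planted pair increases monotonically with modulation depth in every
seed examined.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from kindleictal import benchmarks as bench

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rec = bench.pac_recovery_bench(seed=SEED)
    print(f"planted (8, 80) Hz -> recovered ({rec['f_phase_hat']:.2f}, "
          f"{rec['f_amp_hat']:.2f}) Hz, peak MI {rec['peak_mi']:.4f}, "
          f"within one grid step: {rec['within_one_step']}")

    depths = (0.0, 0.25, 0.5, 0.75, 1.0)
    curves = bench.mi_depth_curves(depths=depths, n_seeds=20, seed=SEED)
    table = pd.DataFrame(
        {
            "depth": depths,
            "mi_median": np.median(curves, axis=0),
            "mi_q25": np.percentile(curves, 25, axis=0),
            "mi_q75": np.percentile(curves, 75, axis=0),
        }
    )
    table.to_csv(RESULTS / "03_mi_vs_depth.csv", index=False)
    pd.DataFrame([{"f_phase_hat": rec["f_phase_hat"],
                   "f_amp_hat": rec["f_amp_hat"],
                   "peak_mi": rec["peak_mi"],
                   "within_one_step": rec["within_one_step"]}]).to_csv(
        RESULTS / "03_pac_recovery.csv", index=False
    )
    print(table.to_string(index=False))
    inc = (np.diff(curves, axis=1) > 0).mean()
    print(f"fraction of adjacent depth steps with increasing MI: {inc:.2f}")


if __name__ == "__main__":
    main()
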
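#!/usr/bin/env python
"""Wavelet phase coherence: phase lock, partial lock, and the noise floor.

Finding (seed 2024): a fully shared narrow-band component gives rho = 1 at
the band frequency, partial locking gives intermediate coherence, and for
independent noise the across-window coherence sits on the analytic
sqrt(pi/(4n)) resultant-length bias.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from kindleictal import benchmarks as bench
from kindleictal.coupling import wpc
from kindleictal.synthdata import SynthConfig, generate_coherent_pair
from kindleictal.wavelet import FrequencyGrid

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    grid = FrequencyGrid(np.array([16.0]), 16, 16, 1)
    for lock in (1.0, 0.7, 0.4, 0.0):
        cfg = SynthConfig(duration=40.0, fs=512.0, seed=SEED, background_sd=1.0)
        a, b = generate_coherent_pair(16.0, lock, cfg)
        cmap = wpc(a, b, grid)
        rows.append(
            {
                "lock_fraction": lock,
                "mean_window_rho": float(np.mean(cmap.rho[0])),
                "band_coherence": cmap.band_coherence(0),
                "n_windows": cmap.n_windows(0),
            }
        )
    table = pd.DataFrame(rows)

    null = bench.wpc_null_bench(n_windows=10, n_reps=200, seed=SEED)
    table.to_csv(RESULTS / "04_wpc_vs_lock.csv", index=False)
    pd.DataFrame([null]).to_csv(RESULTS / "04_wpc_null_bias.csv", index=False)
    print(table.to_string(index=False))
    print(f"\nindependent-noise floor: mean rho {null['mean_rho']:.4f} vs "
          f"analytic sqrt(pi/4n) = {null['expected']:.4f} "
          f"(n = {null['n_windows']} windows, {null['n_reps']} replicates)")


if __name__ == "__main__":
    main()
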
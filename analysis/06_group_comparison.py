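#!/usr/bin/env python
"""Paired two-channel analysis and group-level PAC comparison.

Finding (seed 2024): planted concurrent discharges are recovered in both
channels with onset differences well under a second; the exact
Mann-Whitney comparison reproduces the enumeration p-value for fully
separated groups; and on coupling-free studies the rejection rate matches
the discrete test's achievable level, not the nominal 5 %.
"""

from pathlib import Path

import pandas as pd

from kindleictal import benchmarks as bench
from kindleictal.events import HYP, LVF
from kindleictal.pipeline import PairScenario, compare_groups, report, run_pair_analysis
from kindleictal.synthdata import DischargeSpec

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 2024


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    scenario = PairScenario(
        duration=220.0,
        fs=1000.0,
        seed=SEED,
        shared_specs=(
            DischargeSpec(onset_time=40.0, total_duration=40.0, onset_class=LVF),
            DischargeSpec(onset_time=110.0, total_duration=25.0, onset_class=HYP),
            DischargeSpec(onset_time=165.0, total_duration=30.0, onset_class=LVF,
                          lvf_attenuation=0.5, lvf_length=3.0),
        ),
    )
    analysis = run_pair_analysis(scenario, grid_points_per_octave=2)
    report(analysis, RESULTS / "06_pair_report")
    print(analysis.pairs[["pair_id", "onset_diff_s", "onset_class_a",
                          "onset_class_b", "duration_a", "duration_b"]]
          .to_string(index=False))

    mw = compare_groups([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
    print(f"\nMann-Whitney {{1..5}} vs {{6..10}}: U = {mw.statistic:.0f}, "
          f"exact two-sided p = {mw.p_value:.6f} (2/252 = {2 / 252:.6f})")

    cal = bench.null_calibration_bench(n_studies=200, n_per_group=6, seed=SEED)
    pd.DataFrame([cal]).to_csv(RESULTS / "06_null_calibration.csv", index=False)
    print(f"null rejection rate over {cal['n_studies']} coupling-free studies: "
          f"{cal['rejection_rate']:.3f} (achievable exact level "
          f"{cal['achievable_level']:.4f})")


if __name__ == "__main__":
    main()
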
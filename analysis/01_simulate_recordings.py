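#!/usr/bin/env python
"""Generate the synthetic study recordings and their ground truth.

Writes the planted ground-truth tables to results/ (small CSVs) and the
raw traces to scratch/ (large, regenerable).  Everything downstream can be
regenerated from the seeds printed here.
"""

from pathlib import Path

from kindleictal.events import HYP, LVF, discharge_events_to_frame
from kindleictal.pipeline import PairScenario, generate_pair
from kindleictal.signal_io import write_events, write_trace
from kindleictal.synthdata import DischargeSpec, SliceEventSpec, SynthConfig, generate_slice_trace

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
SEED = 2024

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

slice_cfg = SynthConfig(duration=120.0, fs=5000.0, seed=SEED + 1,
                        background_sd=0.05, spectral_exponent=0.0)
slice_specs = [
    SliceEventSpec("SPW", amplitude=0.15, base_duration=0.05, rate=1.0),
    SliceEventSpec("INTERICTAL", amplitude=0.6, base_duration=0.3, rate=0.3),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    trace_a, trace_b, truth_a, truth_b = generate_pair(scenario)
    write_trace(trace_a, SCRATCH / "pair_hippocampus.csv")
    write_trace(trace_b, SCRATCH / "pair_contralateral.csv")
    import pandas as pd

    truth = pd.concat(
        [discharge_events_to_frame(truth_a), discharge_events_to_frame(truth_b)],
        ignore_index=True,
    )
    write_events(truth, RESULTS / "01_invivo_ground_truth.csv")
    print(f"in-vivo pair: {len(truth_a)} discharges per channel "
          f"({sum(t.onset_class == LVF for t in truth_a)} LVF, "
          f"{sum(t.onset_class == HYP for t in truth_a)} HYP), seed {SEED}")

    slice_trace, slice_truth = generate_slice_trace(slice_specs, slice_cfg)
    write_trace(slice_trace, SCRATCH / "slice_ca3.csv")
    slice_truth.to_csv(RESULTS / "01_slice_ground_truth.csv", index=False)
    print(f"slice trace: {len(slice_truth)} planted field events "
          f"({(slice_truth.kind == 'SPW').sum()} SPWs, "
          f"{(slice_truth.kind == 'INTERICTAL').sum()} interictal spikes)")


if __name__ == "__main__":
    main()
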
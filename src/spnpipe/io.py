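"""Session-bundle file formats.

A session bundle directory holds:

* ``traces.h5`` — datasets ``raw`` and ``background`` (neurons × frames),
  attribute ``frame_rate``;
* ``velocity.csv`` — ``time_s, velocity_cm_s``;
* ``neurons.csv`` — ``neuron_id, red_intensity, true_class, ensemble_flag``;
* ``events_truth.csv`` — ``neuron_id, time_s, amplitude``;
* ``params.json`` — generator-parameter echo.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import VelocityTrace
from .params import SimParams
from .simulate import GroundTruth, SessionBundle
from .traces import TraceMatrix


def write_bundle(bundle: SessionBundle, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "traces.h5", "w") as h5:
        h5.create_dataset("raw", data=bundle.traces.raw, compression="gzip")
        h5.create_dataset("background", data=bundle.traces.background,
                          compression="gzip")
        h5.attrs["frame_rate"] = bundle.traces.frame_rate
    v = bundle.velocity
    pd.DataFrame({"time_s": v.time, "velocity_cm_s": v.velocity}) \
        .to_csv(out / "velocity.csv", index=False)
    bundle.neurons.to_csv(out / "neurons.csv", index=False)
    bundle.truth.events_frame().to_csv(out / "events_truth.csv", index=False)
    bundle.params.to_json(out / "params.json")
    return out


def read_bundle(in_dir) -> SessionBundle:
    src = Path(in_dir)
    params = SimParams.from_json(src / "params.json")
    with h5py.File(src / "traces.h5", "r") as h5:
        traces = TraceMatrix(raw=h5["raw"][:], background=h5["background"][:],
                             frame_rate=float(h5.attrs["frame_rate"]))
    vdf = pd.read_csv(src / "velocity.csv")
    velocity = VelocityTrace(velocity=vdf.velocity_cm_s.to_numpy(),
                             frame_rate=params.frame_rate)
    neurons = pd.read_csv(src / "neurons.csv")
    ev = pd.read_csv(src / "events_truth.csv")
    n = len(neurons)
    times = [np.empty(0)] * n
    amps = [np.empty(0)] * n
    for nid, sub in ev.groupby("neuron_id"):
        times[int(nid)] = sub.time_s.to_numpy()
        amps[int(nid)] = sub.amplitude.to_numpy()
    truth = GroundTruth(
        classes=neurons.true_class.to_numpy(),
        ensemble=neurons.ensemble_flag.to_numpy(dtype=bool),
        red_intensity=neurons.red_intensity.to_numpy(),
        baseline=np.full(n, np.nan),
        event_times=times, event_amps=amps,
        condition_multipliers=params.condition_multipliers,
    )
    return SessionBundle(params=params, velocity=velocity, neurons=neurons,
                         truth=truth, traces=traces)


def write_segments(segments, path) -> None:
    rows = [{"category": "immobility", "start_s": r.start_s, "end_s": r.end_s,
             "onset_s": np.nan, "offset_s": np.nan}
            for r in segments.immobility.itertuples()]
    rows += [{"category": "bout", "start_s": b.candidate_start_s,
              "end_s": b.candidate_end_s, "onset_s": b.onset_s,
              "offset_s": b.offset_s}
             for b in segments.bouts.itertuples()]
    pd.DataFrame(rows, columns=["category", "start_s", "end_s",
                                "onset_s", "offset_s"]).to_csv(path, index=False)


def write_provenance(path, config: dict, seed: int) -> None:
    import spnpipe

    record = {"config": config, "seed": seed,
              "versions": {"spnpipe": spnpipe.__version__,
                           "numpy": np.__version__,
                           "pandas": pd.__version__}}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
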
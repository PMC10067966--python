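"""Session serialization: HDF5 containers and plain-text tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .neural import SessionData
from .task import Trial


def trial_table(trials: list[Trial]) -> pd.DataFrame:
    """One row per trial: targets, responses, outcome, condition, events."""
    rows = []
    for t in trials:
        rows.append({
            "trial_id": t.trial_id,
            "target_r": t.target_polar[0], "target_theta": t.target_polar[1],
            "response_r": t.response_polar[0], "response_theta": t.response_polar[1],
            "rewarded": t.rewarded, "condition": t.condition,
            "excluded": t.excluded,
            **{f"t_{k}": v for k, v in t.events.items()},
        })
    return pd.DataFrame(rows)


def save_session(path: str | Path, session: SessionData) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["dt"] = session.dt
        f.attrs["sample_rate"] = session.trials[0].sample_rate if session.trials else 0.0
        f.create_dataset("trial_slices", data=np.asarray(session.trial_slices))
        f.create_dataset("counts", data=session.counts, compression="gzip")
        sg = f.create_group("signals")
        for k, v in session.signals.items():
            sg.create_dataset(k, data=v, compression="gzip")
        eg = f.create_group("events")
        for k, v in session.events.items():
            eg.create_dataset(k, data=v, compression="gzip")
        ug = f.create_group("units")
        for i, st in enumerate(session.spike_times):
            g = ug.create_group(str(i))
            g.create_dataset("spike_times", data=st)
            if session.electrode_pos is not None:
                g.create_dataset("electrode", data=session.electrode_pos[i])
        tg = f.create_group("trials")
        for k, tr in enumerate(session.trials):
            g = tg.create_group(str(k))
            g.attrs["sample_rate"] = tr.sample_rate
            for name, arr in (("v", tr.linear_velocity), ("omega", tr.angular_velocity),
                              ("x", tr.position[:, 0]), ("y", tr.position[:, 1]),
                              ("heading", tr.heading)):
                g.create_dataset(name, data=arr, compression="gzip")
            g.attrs["meta"] = json.dumps({
                "trial_id": tr.trial_id, "target_polar": tr.target_polar,
                "response_polar": tr.response_polar, "rewarded": bool(tr.rewarded),
                "condition": tr.condition, "events": tr.events,
                "excluded": bool(tr.excluded), "timed_out": bool(tr.timed_out),
            })


def load_session(path: str | Path) -> SessionData:
    with h5py.File(path, "r") as f:
        dt = float(f.attrs["dt"])
        slices = [tuple(map(int, row)) for row in f["trial_slices"][()]]
        counts = f["counts"][()]
        signals = {k: f["signals"][k][()] for k in f["signals"]}
        events = {k: f["events"][k][()] for k in f["events"]}
        spike_times, elec = [], []
        for i in sorted(f["units"], key=int):
            g = f["units"][i]
            spike_times.append(g["spike_times"][()])
            if "electrode" in g:
                elec.append(g["electrode"][()])
        trials = []
        for k in sorted(f["trials"], key=int):
            g = f["trials"][k]
            meta = json.loads(g.attrs["meta"])
            pos = np.column_stack([g["x"][()], g["y"][()]])
            trials.append(Trial(
                trial_id=meta["trial_id"],
                target_polar=tuple(meta["target_polar"]),
                linear_velocity=g["v"][()], angular_velocity=g["omega"][()],
                position=pos, heading=g["heading"][()],
                cmd_linear=np.zeros(0), cmd_angular=np.zeros(0),
                events=meta["events"],
                response_polar=tuple(meta["response_polar"]),
                rewarded=meta["rewarded"], condition=meta["condition"],
                timed_out=meta["timed_out"], excluded=meta["excluded"],
                sample_rate=float(g.attrs["sample_rate"]),
            ))
    return SessionData(dt=dt, trials=trials, trial_slices=slices, counts=counts,
                       spike_times=spike_times, signals=signals, events=events,
                       electrode_pos=np.asarray(elec) if elec else None)
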
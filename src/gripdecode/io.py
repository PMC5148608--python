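"""Plain-text session containers and feature tables.

A session directory holds ``signals.tsv`` (time + 4 contacts + force),
``events.csv`` (cue_time_s, sre), ``meta.json`` and, for synthetic
sessions, ``ground_truth.json`` plus ``true_envelopes.tsv``.  Feature
tables are long-format CSVs with one row per (trial, time point).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from gripdecode.exceptions import InputError
from gripdecode.features import BandPowerTrace, ContinuousRecording, Trial

__all__ = [
    "write_session",
    "read_session",
    "write_features",
    "read_features",
    "write_tfmap",
]

SIGNAL_COLUMNS = ["time_s", "contact0", "contact1", "contact2", "contact3", "force"]


def write_session(out_dir, session_or_recording) -> Path:
    """Write a recording (or a full SyntheticSession) as a text container."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec = getattr(session_or_recording, "recording", session_or_recording)

    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame(
        dict(zip(SIGNAL_COLUMNS, [t, *rec.monopolar, rec.force]))
    )
    df.to_csv(out / "signals.tsv", sep="\t", index=False, float_format="%.6g")
    pd.DataFrame({"cue_time_s": rec.cue_times, "sre": rec.sre}).to_csv(
        out / "events.csv", index=False
    )
    (out / "meta.json").write_text(
        json.dumps({"fs": rec.fs, "meta": rec.meta}, indent=2)
    )

    session = session_or_recording if hasattr(session_or_recording, "true_params") else None
    if session is not None:
        gt = {
            "true_model_id": session.true_model_id,
            "true_params": np.asarray(session.true_params).tolist(),
            "config": dataclasses.asdict(session.config),
        }
        gt["config"]["sre_levels"] = (
            None
            if session.config.sre_levels is None
            else list(map(int, session.config.sre_levels))
        )
        (out / "ground_truth.json").write_text(json.dumps(gt, indent=2, default=list))
        rows = []
        for i, env in enumerate(session.true_envelopes):
            rows.append(
                pd.DataFrame(
                    {
                        "trial": i,
                        "time_s": env.times,
                        "alpha": env.alpha,
                        "beta": env.beta,
                        "gamma": env.gamma,
                        "true_force": session.true_force[i],
                        "observed_force": session.observed_force[i],
                    }
                )
            )
        pd.concat(rows).to_csv(
            out / "true_envelopes.tsv", sep="\t", index=False, float_format="%.8g"
        )
    return out


def read_session(session_dir) -> ContinuousRecording:
    """Read a text session container back into a ContinuousRecording."""
    d = Path(session_dir)
    sig = d / "signals.tsv"
    if not sig.exists():
        raise InputError(f"no signals.tsv in {d}")
    df = pd.read_csv(sig, sep="\t")
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"signals.tsv missing columns {missing}")
    events = pd.read_csv(d / "events.csv")
    meta = json.loads((d / "meta.json").read_text()) if (d / "meta.json").exists() else {}
    t = df["time_s"].to_numpy()
    fs = meta.get("fs") or 1.0 / float(np.median(np.diff(t)))
    return ContinuousRecording(
        monopolar=df[SIGNAL_COLUMNS[1:5]].to_numpy().T,
        force=df["force"].to_numpy(),
        fs=float(fs),
        cue_times=events["cue_time_s"].to_numpy(),
        sre=events["sre"].to_numpy(),
        meta=meta.get("meta", {}),
    )


def write_features(trials: list[Trial], path, pair: str | None = None) -> Path:
    """Long-format per-trial feature table (one row per time point)."""
    rows = []
    for i, tr in enumerate(trials):
        bt = tr.band_trace
        rows.append(
            pd.DataFrame(
                {
                    "trial": i,
                    "sre": tr.sre,
                    "time_s": bt.times,
                    "alpha": bt.alpha,
                    "beta": bt.beta,
                    "gamma": bt.gamma,
                    "force": tr.force,
                }
            )
        )
    df = pd.concat(rows)
    if pair is not None:
        df.insert(0, "pair", pair)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def read_features(path) -> list[Trial]:
    df = pd.read_csv(path)
    trials = []
    for idx, g in df.groupby("trial", sort=True):
        bt = BandPowerTrace(
            alpha=g["alpha"].to_numpy(),
            beta=g["beta"].to_numpy(),
            gamma=g["gamma"].to_numpy(),
            times=g["time_s"].to_numpy(),
        )
        trials.append(
            Trial(
                band_trace=bt,
                force=g["force"].to_numpy(),
                sre=int(g["sre"].iloc[0]),
                cue_time=float("nan"),
            )
        )
    return trials


def write_tfmap(tf, path) -> Path:
    """Store a time-frequency map in an HDF5 container."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("freqs", data=tf.freqs)
        f.create_dataset("times", data=tf.times)
        f.create_dataset("power", data=tf.power, compression="gzip")
        if tf.edge_mask is not None:
            f.create_dataset("edge_mask", data=tf.edge_mask, compression="gzip")
    return path
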
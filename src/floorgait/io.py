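"""Disk formats: HDF5 recordings, CSV annotation/feature/label tables.

A simulated cohort is stored as one HDF5 file (one dataset per sensor
recording, with sampling rate, position and noise-reference attributes)
plus flat CSV tables for annotations and biometrics, so every artifact
is inspectable with standard tools.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .records import (
    Biometrics,
    FootstepImpulse,
    GroundTruthAnnotations,
    SensorRecording,
    SubjectData,
    WalkTrace,
)

__all__ = [
    "write_cohort",
    "read_cohort",
    "annotations_table",
    "biometrics_table",
    "impulse_table",
]


def write_cohort(path: str | Path, cohort: list[SubjectData]) -> None:
    """Write a cohort to HDF5: subjects/<i>/traces/<j>/sensors/<k>."""
    with h5py.File(path, "w") as f:
        for subject in cohort:
            g = f.create_group(f"subjects/{subject.subject_id}")
            g.attrs.update(
                {
                    "age": subject.biometrics.age,
                    "weight": subject.biometrics.weight,
                    "height": subject.biometrics.height,
                    "gender": subject.biometrics.gender,
                    "run_time_100m": subject.run_time_100m,
                    "stage": subject.stage,
                }
            )
            for j, trace in enumerate(subject.traces):
                tg = g.create_group(f"traces/{j}")
                ann = trace.annotations
                tg.attrs["stage_label"] = ann.stage_label
                tg.create_dataset("strike_times", data=ann.strike_times)
                tg.create_dataset("peak_forces", data=ann.peak_forces)
                tg.create_dataset(
                    "contact_types",
                    data=np.array(ann.contact_types, dtype="S8"),
                )
                for rec in trace.recordings:
                    d = tg.create_dataset(
                        f"sensors/{rec.sensor_id}", data=rec.samples
                    )
                    d.attrs["sampling_rate"] = rec.sampling_rate
                    d.attrs["sensor_id"] = rec.sensor_id
                    if rec.position is not None:
                        d.attrs["position"] = rec.position
                    if rec.noise_reference is not None:
                        d.attrs["noise_reference"] = rec.noise_reference


def read_cohort(path: str | Path) -> list[SubjectData]:
    """Read a cohort written by :func:`write_cohort`."""
    cohort = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"], key=int):
            g = f[f"subjects/{sid}"]
            bio = Biometrics(
                age=float(g.attrs["age"]),
                weight=float(g.attrs["weight"]),
                height=float(g.attrs["height"]),
                gender=str(g.attrs["gender"]),
            )
            traces = []
            for j in sorted(g["traces"], key=int):
                tg = g[f"traces/{j}"]
                recordings = []
                for k in sorted(tg["sensors"], key=int):
                    d = tg[f"sensors/{k}"]
                    noise_ref = d.attrs.get("noise_reference")
                    recordings.append(
                        SensorRecording(
                            samples=d[()],
                            sampling_rate=float(d.attrs["sampling_rate"]),
                            sensor_id=int(d.attrs["sensor_id"]),
                            noise_reference=tuple(int(v) for v in noise_ref)
                            if noise_ref is not None
                            else None,
                            position=float(d.attrs["position"])
                            if "position" in d.attrs
                            else None,
                        )
                    )
                ann = GroundTruthAnnotations(
                    strike_times=tg["strike_times"][()],
                    contact_types=[
                        c.decode() for c in tg["contact_types"][()]
                    ],
                    peak_forces=tg["peak_forces"][()],
                    stage_label=int(tg.attrs["stage_label"]),
                    biometrics=bio,
                )
                traces.append(WalkTrace(recordings=recordings, annotations=ann))
            cohort.append(
                SubjectData(
                    subject_id=int(sid),
                    biometrics=bio,
                    run_time_100m=float(g.attrs["run_time_100m"]),
                    stage=int(g.attrs["stage"]),
                    traces=traces,
                )
            )
    return cohort


def annotations_table(cohort: list[SubjectData]) -> pd.DataFrame:
    """One row per annotated footstep: subject, trace, strike time, contact."""
    rows = []
    for subject in cohort:
        for j, trace in enumerate(subject.traces):
            ann = trace.annotations
            for i in range(ann.n_steps):
                rows.append(
                    {
                        "subject_id": subject.subject_id,
                        "trace_id": j,
                        "footstep": i + 1,
                        "strike_time_s": ann.strike_times[i],
                        "contact_type": ann.contact_types[i],
                        "peak_force": ann.peak_forces[i],
                        "stage": ann.stage_label,
                    }
                )
    return pd.DataFrame(rows)


def biometrics_table(cohort: list[SubjectData]) -> pd.DataFrame:
    """One row per subject: biometrics, 100-m run time and stage label."""
    return pd.DataFrame(
        {
            "subject_id": s.subject_id,
            "age_years": s.biometrics.age,
            "weight_kg": s.biometrics.weight,
            "height_m": s.biometrics.height,
            "gender": s.biometrics.gender,
            "run_time_100m_s": s.run_time_100m,
            "stage": s.stage,
        }
        for s in cohort
    )


def impulse_table(impulses: list[FootstepImpulse]) -> pd.DataFrame:
    """Detected-impulse event table (sensor, onset, offset, index, clipped)."""
    return pd.DataFrame(
        {
            "sensor_id": imp.sensor_id,
            "onset_s": imp.onset_time,
            "offset_s": imp.offset_time,
            "index_in_trace": imp.index_in_trace,
            "clipped": imp.clipped,
        }
        for imp in impulses
    )
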
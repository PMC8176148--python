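"""HDF5/CSV persistence for cohorts, epochs and derived tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocessing import SensorRecording
from .synthetic import SubjectMetadata


def save_cohort(
    path: str | Path,
    metadata: list[SubjectMetadata],
    recordings: dict[str, SensorRecording],
    source_truth: dict[str, np.ndarray] | None = None,
) -> None:
    """One HDF5 group per subject: sensor data, head trace, ground truth."""
    with h5py.File(path, "w") as f:
        for m in metadata:
            g = f.create_group(m.subject_id)
            g.attrs.update(
                {"group": m.group, "age": m.age, "sex": m.sex, "head_motion": m.head_motion}
            )
            rec = recordings[m.subject_id]
            g.create_dataset("sensor_data", data=rec.data, compression="gzip")
            g.create_dataset("head_position", data=rec.head_position_trace, compression="gzip")
            g.attrs["sampling_rate"] = rec.sampling_rate
            if source_truth and m.subject_id in source_truth:
                g.create_dataset("source_truth", data=source_truth[m.subject_id],
                                 compression="gzip")


def load_cohort(path: str | Path) -> tuple[list[SubjectMetadata], dict[str, SensorRecording]]:
    metadata, recordings = [], {}
    with h5py.File(path, "r") as f:
        for sid in sorted(f.keys()):
            g = f[sid]
            metadata.append(
                SubjectMetadata(
                    subject_id=sid,
                    group=str(g.attrs["group"]),
                    age=float(g.attrs["age"]),
                    sex=str(g.attrs["sex"]),
                    head_motion=float(g.attrs["head_motion"]),
                )
            )
            recordings[sid] = SensorRecording(
                data=g["sensor_data"][()],
                sampling_rate=float(g.attrs["sampling_rate"]),
                head_position_trace=g["head_position"][()],
                subject_id=sid,
            )
    return metadata, recordings


def metadata_to_csv(metadata: list[SubjectMetadata], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"subject_id": m.subject_id, "group": m.group, "age": m.age,
             "sex": m.sex, "head_motion": m.head_motion}
            for m in metadata
        ]
    )
    df.to_csv(path, index=False)
    return df


def save_source_epochs(path: str | Path, epochs_by_subject: dict[str, np.ndarray],
                       fs: float, labels: list[str]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["sampling_rate"] = fs
        f.attrs["labels"] = labels or [""]
        for sid, arr in epochs_by_subject.items():
            f.create_dataset(sid, data=arr, compression="gzip")


def load_source_epochs(path: str | Path) -> tuple[dict[str, np.ndarray], float, list[str]]:
    out = {}
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sampling_rate"])
        labels = [l.decode() if isinstance(l, bytes) else str(l)
                  for l in f.attrs["labels"]]
        for sid in sorted(f.keys()):
            out[sid] = f[sid][()]
    return out, fs, labels


def save_connectivity(path: str | Path, conn_by_subject: dict[str, np.ndarray],
                      band_names: list[str]) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["bands"] = list(band_names)
        for sid, arr in conn_by_subject.items():
            f.create_dataset(sid, data=arr, compression="gzip")


def load_connectivity(path: str | Path) -> tuple[dict[str, np.ndarray], list[str]]:
    out = {}
    with h5py.File(path, "r") as f:
        bands = [b.decode() if isinstance(b, bytes) else str(b)
                 for b in f.attrs["bands"]]
        for sid in sorted(f.keys()):
            out[sid] = f[sid][()]
    return out, bands


def statmap_to_csv(statmap: pd.DataFrame, path: str | Path) -> None:
    df = statmap.copy()
    df["unit"] = df["unit"].apply(
        lambda u: f"{u[0]}-{u[1]}" if isinstance(u, tuple) else u
    )
    df.to_csv(path, index=False)


def edge_list_csv(matrix: np.ndarray, path: str | Path) -> None:
    """Upper-triangle (i < j, 0-based) edge list of one connectivity matrix."""
    iu = np.triu_indices(matrix.shape[0], k=1)
    pd.DataFrame(
        {"seed_i": iu[0], "seed_j": iu[1], "value": matrix[iu]}
    ).to_csv(path, index=False)
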
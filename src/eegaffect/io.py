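"""Readers and writers for recordings, label tables and epoch archives.

Two input formats are supported: European Data Format (EDF, via mne) and
a plain-text CSV bridge — one row per channel, first column the 10-20
electrode label, remaining columns the samples, with a JSON side-car
(``<file>.json``) holding the sampling rate and trial identifiers.
Restricted-dataset releases (DEAP .dat, AMIGOS .mat) are not parsed; any
tool that can dump a numeric matrix can produce the CSV bridge.

Labels come either from the side-car or from a separate CSV table with
columns ``subject_id, trial_id, valence_raw, arousal_raw, scale_min,
scale_max``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelMismatchError, EEGAffectError, LabelError
from .montage import Montage
from .recording import AffectLabel, Epoch, Recording

__all__ = [
    "read_recording",
    "read_label_table",
    "write_recording_csv",
    "save_epochs",
    "load_epochs",
]


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Load a per-trial label table keyed by (subject_id, trial_id)."""
    table = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str})
    required = {"subject_id", "trial_id", "valence_raw", "arousal_raw"}
    missing = required - set(table.columns)
    if missing:
        raise LabelError(f"label table missing columns: {sorted(missing)}")
    if "scale_min" not in table.columns:
        table["scale_min"] = 1.0
    if "scale_max" not in table.columns:
        table["scale_max"] = 9.0
    return table


def _label_from_row(row) -> AffectLabel:
    return AffectLabel(
        valence_raw=float(row["valence_raw"]),
        arousal_raw=float(row["arousal_raw"]),
        scale_min=float(row["scale_min"]),
        scale_max=float(row["scale_max"]),
    )


def _lookup_label(
    label_source: pd.DataFrame, subject_id: str, trial_id: str
) -> AffectLabel:
    hit = label_source[
        (label_source["subject_id"] == subject_id)
        & (label_source["trial_id"] == trial_id)
    ]
    if len(hit) != 1:
        raise LabelError(
            f"expected exactly one label row for ({subject_id}, {trial_id}), "
            f"found {len(hit)}"
        )
    return _label_from_row(hit.iloc[0])


def _reorder(data: np.ndarray, file_channels: list[str], montage: Montage) -> np.ndarray:
    index = {name: i for i, name in enumerate(file_channels)}
    missing = [c for c in montage.channels if c not in index]
    if missing:
        raise ChannelMismatchError(
            f"file lacks montage channels {missing}; file has {file_channels}"
        )
    return data[[index[c] for c in montage.channels], :]


def read_recording(
    path: str | Path,
    format: str,
    montage: Montage,
    label_source: pd.DataFrame | AffectLabel | None = None,
) -> Recording:
    """Read one trial recording, reordering channels to montage order.

    ``label_source`` may be an :class:`AffectLabel`, a label table
    (DataFrame), or None — in which case labels must be present in the
    CSV side-car.
    """
    path = Path(path)
    if not path.exists():
        raise EEGAffectError(f"no such file: {path}")
    if format == "csv":
        return _read_csv(path, montage, label_source)
    if format == "edf":
        return _read_edf(path, montage, label_source)
    raise EEGAffectError(f"unknown format {format!r}; use 'csv' or 'edf'")


def _read_csv(
    path: Path, montage: Montage, label_source
) -> Recording:
    frame = pd.read_csv(path)
    if frame.columns[0] != "channel":
        raise EEGAffectError("CSV bridge requires a leading 'channel' column")
    file_channels = frame["channel"].astype(str).tolist()
    data = frame.drop(columns="channel").to_numpy(dtype=np.float64)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise EEGAffectError(f"missing side-car {sidecar}")
    meta = json.loads(sidecar.read_text())
    fs = float(meta["fs"])
    subject_id = str(meta.get("subject_id", "s0"))
    trial_id = str(meta.get("trial_id", "trial0"))
    labels = _resolve_labels(label_source, meta, subject_id, trial_id)
    return Recording(
        data=_reorder(data, file_channels, montage),
        fs=fs,
        montage=montage,
        labels=labels,
        trial_id=trial_id,
        subject_id=subject_id,
    )


def _read_edf(path: Path, montage: Montage, label_source) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise EEGAffectError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne loads volts; recordings are in microvolts
    subject_id = str(path.stem)
    trial_id = "trial0"
    if not isinstance(label_source, (AffectLabel, pd.DataFrame)):
        raise LabelError("EDF files carry no affect labels; pass label_source")
    labels = _resolve_labels(label_source, {}, subject_id, trial_id)
    return Recording(
        data=_reorder(data, list(raw.ch_names), montage),
        fs=float(raw.info["sfreq"]),
        montage=montage,
        labels=labels,
        trial_id=trial_id,
        subject_id=subject_id,
    )


def _resolve_labels(label_source, meta: dict, subject_id: str, trial_id: str) -> AffectLabel:
    if isinstance(label_source, AffectLabel):
        return label_source
    if isinstance(label_source, pd.DataFrame):
        return _lookup_label(label_source, subject_id, trial_id)
    if "labels" in meta:
        lab = meta["labels"]
        try:
            return AffectLabel(
                valence_raw=float(lab["valence_raw"]),
                arousal_raw=float(lab["arousal_raw"]),
                scale_min=float(lab.get("scale_min", 1.0)),
                scale_max=float(lab.get("scale_max", 9.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise LabelError(f"unreadable labels in side-car: {lab!r}") from exc
    raise LabelError(f"no labels for ({subject_id}, {trial_id})")


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write a recording in the CSV bridge format (matrix + JSON side-car)."""
    path = Path(path)
    frame = pd.DataFrame(rec.data, copy=False)
    frame.insert(0, "channel", list(rec.montage.channels))
    frame.to_csv(path, index=False)
    meta = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "montage": rec.montage.name,
        "labels": {
            "valence_raw": rec.labels.valence_raw,
            "arousal_raw": rec.labels.arousal_raw,
            "scale_min": rec.labels.scale_min,
            "scale_max": rec.labels.scale_max,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def save_epochs(epochs: list[Epoch], directory: str | Path) -> None:
    """Persist epochs as a directory of CSV matrices plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, ep in enumerate(epochs):
        fname = f"epoch_{i:05d}.csv"
        frame = pd.DataFrame(ep.data, copy=False)
        frame.insert(0, "channel", list(ep.montage.channels))
        frame.to_csv(directory / fname, index=False)
        manifest.append(
            {
                "file": fname,
                "fs": ep.fs,
                "montage": ep.montage.name,
                "subject_id": ep.subject_id,
                "trial_id": ep.trial_id,
                "epoch_index": ep.epoch_index,
                "labels": {
                    "valence_raw": ep.labels.valence_raw,
                    "arousal_raw": ep.labels.arousal_raw,
                    "scale_min": ep.labels.scale_min,
                    "scale_max": ep.labels.scale_max,
                },
            }
        )
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_epochs(directory: str | Path, montage: Montage) -> list[Epoch]:
    """Load an epoch directory written by :func:`save_epochs`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    epochs = []
    for entry in manifest:
        frame = pd.read_csv(directory / entry["file"])
        data = _reorder(
            frame.drop(columns="channel").to_numpy(dtype=np.float64),
            frame["channel"].astype(str).tolist(),
            montage,
        )
        lab = entry["labels"]
        epochs.append(
            Epoch(
                data=data,
                fs=float(entry["fs"]),
                montage=montage,
                labels=AffectLabel(
                    lab["valence_raw"], lab["arousal_raw"],
                    lab["scale_min"], lab["scale_max"],
                ),
                trial_id=entry["trial_id"],
                subject_id=entry["subject_id"],
                epoch_index=int(entry["epoch_index"]),
            )
        )
    return epochs
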
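"""File formats: BrainVision/EDF recordings, epoch containers, tables, models.

Recordings are read through MNE (BrainVision ``.vhdr`` triplets and EDF).
Synthetic recordings are written as BrainVision files by a small writer of
our own — an INI text header (``.vhdr``), a marker file (``.vmrk``) and
multiplexed IEEE float32 binary data (``.eeg``) — which MNE reads back
losslessly. Epoch sets travel as ``.npz`` containers with a JSON provenance
sidecar; microstate models as channel-labeled JSON; subject tables as strict
UTF-8 CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .microstates import MicrostateModel
from .preprocess import EEGRecording, EpochSet

__all__ = [
    "write_brainvision",
    "read_recording",
    "write_epochs",
    "read_epochs",
    "model_to_json",
    "model_from_json",
    "read_subject_table",
    "write_subject_table",
]

_CONDITION_TAGS = ("eyes_closed", "eyes_open")


def write_brainvision(rec: EEGRecording, basepath: str | Path) -> Path:
    """Write `rec` as a BrainVision triplet; returns the ``.vhdr`` path.

    Data go out as multiplexed IEEE float32 in uV; annotations become
    ``Comment`` markers (1-based positions, length in sampling points).
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name.removesuffix(".vhdr")
    vhdr, vmrk, eeg = (base.parent / f"{stem}{ext}" for ext in (".vhdr", ".vmrk", ".eeg"))

    sampling_interval_us = 1e6 / rec.sfreq
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(rec.labels, start=1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for j, (onset, duration, tag) in enumerate(rec.annotations, start=2):
        pos = int(round(onset * rec.sfreq)) + 1  # 1-based
        length = int(round(duration * rec.sfreq))
        mlines.append(f"Mk{j}=Comment,{tag},{pos},{length},0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    rec.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major
    return vhdr


def read_recording(path: str | Path) -> EEGRecording:
    """Read a BrainVision ``.vhdr`` or EDF file into an :class:`EEGRecording`.

    Channel data are converted to uV. Marker/annotation descriptions
    containing ``eyes_closed`` / ``eyes_open`` are mapped to those condition
    tags; everything else is tagged ``other``.
    """
    import mne

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if path.suffix.lower() == ".vhdr":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        elif path.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raise ValueError(f"unsupported recording format: {path.suffix}")
    data_uv = raw.get_data() * 1e6  # MNE uses volts internally
    annotations = []
    for ann in raw.annotations:
        desc = ann["description"]
        tag = next((t for t in _CONDITION_TAGS if t in desc), None)
        if tag is None:
            if "New Segment" in desc:
                continue
            tag = "other"
        annotations.append((float(ann["onset"]), float(ann["duration"]), tag))
    return EEGRecording(
        data=data_uv,
        sfreq=float(raw.info["sfreq"]),
        labels=tuple(raw.ch_names),
        annotations=annotations,
    )


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Save an epoch set as ``.npz`` plus a ``.provenance.json`` sidecar."""
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        epochs=epochs.epochs,
        sfreq=epochs.sfreq,
        epoch_length=epochs.epoch_length,
        labels=np.array(epochs.labels),
        reference=epochs.reference,
    )
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(json.dumps(epochs.provenance, indent=2, default=str), encoding="utf-8")
    return path


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    with np.load(path, allow_pickle=False) as z:
        prov_path = path.with_suffix(".provenance.json")
        provenance = (
            json.loads(prov_path.read_text(encoding="utf-8")) if prov_path.exists() else {}
        )
        return EpochSet(
            epochs=z["epochs"],
            sfreq=float(z["sfreq"]),
            epoch_length=float(z["epoch_length"]),
            labels=tuple(z["labels"].tolist()),
            reference=str(z["reference"]),
            provenance=provenance,
        )


def model_to_json(model: MicrostateModel, channel_labels, path: str | Path) -> Path:
    """Serialize a microstate model as channel-labeled JSON."""
    path = Path(path)
    payload = {
        "level": model.level,
        "gev_total": model.gev_total,
        "channels": list(channel_labels),
        "maps": {
            name: {
                "values": model.maps[i].tolist(),
                "gev": float(model.gev_per_map[i]),
            }
            for i, name in enumerate(model.labels)
        },
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return path


def model_from_json(path: str | Path) -> tuple[MicrostateModel, tuple[str, ...]]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    names = tuple(payload["maps"].keys())
    maps = np.array([payload["maps"][n]["values"] for n in names])
    gev = np.array([payload["maps"][n]["gev"] for n in names])
    model = MicrostateModel(
        maps=maps,
        labels=names,
        gev_per_map=gev,
        gev_total=float(payload["gev_total"]),
        level=payload.get("level", "subject"),
    )
    return model, tuple(payload["channels"])


_AQ_ITEM_COLS = tuple(f"aq_item_{j:02d}" for j in range(1, 13))


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a subject table CSV.

    Required columns: ``subject_id``, ``gender`` and the twelve AQ items
    (integers in 1..6). Unknown columns are preserved with a warning;
    schema violations raise with the offending columns named.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in ("subject_id", "gender", *_AQ_ITEM_COLS) if c not in df.columns]
    if missing:
        raise ValueError(f"subject table missing required columns: {missing}")
    bad_items = []
    for c in _AQ_ITEM_COLS:
        v = df[c]
        if v.isna().any() or not np.all((v >= 1) & (v <= 6) & (v == v.round())):
            bad_items.append(c)
    if bad_items:
        raise ValueError(
            f"AQ items must be integers in 1..6; offending columns: {bad_items}"
        )
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id values")
    extra = [
        c
        for c in df.columns
        if c not in ("subject_id", "gender", *_AQ_ITEM_COLS)
        and not c.startswith(("duration_", "occurrence_", "coverage_", "mean_", "gev", "aq_"))
    ]
    if extra:
        warnings.warn(f"unknown subject-table columns preserved: {extra}", stacklevel=2)
    return df


def write_subject_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")
    return path
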
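"""Readers, writers and run manifests.

Real recordings enter through MNE (EDF/BDF and BrainVision); the rest of
the pipeline exchanges long-format CSV tables and JSON reports.  Network
stacks can additionally be stored as a compressed array container, but
CSV remains the canonical copy.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import PLINetworkStack
from .montage import MontageSpec
from .preprocess import Recording


def from_mne_raw(raw, montage: MontageSpec) -> Recording:
    """Convert an ``mne.io.Raw`` object into a :class:`Recording`.

    Channel labels must cover the montage (network + reference labels);
    extra channels in the raw object are ignored.  Data are converted
    from MNE's volts to microvolts.
    """
    available = set(raw.ch_names)
    wanted = list(montage.all_labels)
    missing = [lab for lab in wanted if lab not in available]
    if missing:
        raise ValueError(
            f"recording is missing montage channels {missing}; "
            f"available: {sorted(available)}"
        )
    data = raw.get_data(picks=wanted) * 1e6
    return Recording(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        montage=montage,
        has_references=True,
    )


def read_recording(path: str | Path, montage: MontageSpec) -> Recording:
    """Read an EDF/BDF or BrainVision recording into montage order."""
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error") \
            if suffix == ".edf" else mne.io.read_raw_bdf(path, preload=True, verbose="error")
    elif suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(
            f"unsupported recording format {suffix!r}; expected .edf, .bdf or .vhdr"
        )
    return from_mne_raw(raw, montage)


def to_mne_raw(recording: Recording):
    """Wrap a :class:`Recording` as an ``mne.io.RawArray`` (microvolts -> volts)."""
    import mne

    info = mne.create_info(
        ch_names=list(recording.channel_labels),
        sfreq=recording.sampling_rate,
        ch_types="eeg",
    )
    return mne.io.RawArray(recording.data * 1e-6, info, verbose="error")


def export_edf(recording: Recording, path: str | Path) -> None:
    """Export a recording as EDF via MNE (requires the ``edfio`` backend)."""
    raw = to_mne_raw(recording)
    try:
        raw.export(str(path), fmt="edf", overwrite=True, verbose="error")
    except (ImportError, ModuleNotFoundError, RuntimeError) as exc:
        raise RuntimeError(
            "EDF export needs MNE's EDF writer backend (pip install edfio)"
        ) from exc


def stacks_to_frame(stacks: list[PLINetworkStack]) -> pd.DataFrame:
    """Long-format edge table: (subject, band, epoch, chan_a, chan_b, pli)."""
    frames = []
    for stack in stacks:
        pairs = list(stack.montage.edges())
        chan_a = np.array([a for a, _ in pairs])
        chan_b = np.array([b for _, b in pairs])
        n_edges = len(pairs)
        for row, epoch_idx in enumerate(stack.epoch_indices):
            frames.append(pd.DataFrame({
                "subject": stack.subject_id,
                "band": stack.band,
                "epoch": int(epoch_idx),
                "chan_a": chan_a,
                "chan_b": chan_b,
                "pli": stack.weights[row],
            }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["subject", "band", "epoch", "chan_a", "chan_b", "pli"]
    )


def save_stacks_npz(stacks: list[PLINetworkStack], path: str | Path) -> None:
    """Array container: one ``epochs x 1891`` array per (subject, band)."""
    if not stacks:
        raise ValueError("no stacks to save")
    arrays = {}
    for stack in stacks:
        key = f"{stack.subject_id}__{stack.band}"
        arrays[f"weights__{key}"] = stack.weights
        arrays[f"epochs__{key}"] = stack.epoch_indices
    arrays["channel_labels"] = np.array(stacks[0].montage.labels)
    np.savez_compressed(path, **arrays)


def load_stacks_npz(path: str | Path, montage: MontageSpec) -> list[PLINetworkStack]:
    with np.load(path, allow_pickle=False) as data:
        labels = tuple(str(x) for x in data["channel_labels"])
        if labels != montage.labels:
            raise ValueError("stored channel labels do not match the montage")
        stacks = []
        for key in sorted(k for k in data.files if k.startswith("weights__")):
            _, subject, band = key.split("__")
            stacks.append(PLINetworkStack(
                subject_id=subject,
                band=band,
                epoch_indices=data[key.replace("weights__", "epochs__")],
                weights=data[key],
                montage=montage,
            ))
    return stacks


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json_atomic(payload: dict, path: str | Path) -> None:
    """Write JSON via a temp file + rename so readers never see partial files."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def build_manifest(config_snapshot: dict, seeds: dict, outputs: dict[str, Path],
                   version: str) -> dict:
    """Run manifest: config snapshot, seeds, software version, file checksums."""
    return {
        "software": {"name": "plidrift", "version": version},
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": config_snapshot,
        "seeds": seeds,
        "outputs": {
            name: {"path": str(p), "sha256": sha256_of(p)}
            for name, p in outputs.items() if Path(p).exists()
        },
    }
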
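"""Epoched EEG container with HDF5 round-tripping.

The on-disk schema is a plain HDF5 file with datasets ``/data`` (trials x
channels x samples, microvolt), ``/labels`` and ``/blocks`` (one integer per
trial) and root attributes ``fs``, ``channels`` and ``latency_corrected``.  A
JSON sidecar (same stem, ``.json`` suffix) mirrors the attributes so the
metadata stays greppable without an HDF5 reader.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np


@dataclass
class EpochSet:
    """Trials x channels x samples tensor plus acquisition metadata."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), microvolt
    fs: float  # Hz
    labels: np.ndarray  # target_id per trial
    blocks: np.ndarray  # acquisition block id per trial
    channels: list[str]
    latency_corrected: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.blocks = np.asarray(self.blocks, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_channels, _ = self.data.shape
        if len(self.labels) != n_trials or len(self.blocks) != n_trials:
            raise ValueError("labels/blocks length must match n_trials")
        if len(self.channels) != n_channels:
            raise ValueError("channel name count must match n_channels")
        if len(set(self.channels)) != n_channels:
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoch data contains NaN or Inf")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            labels=self.labels[mask],
            blocks=self.blocks[mask],
            channels=list(self.channels),
            latency_corrected=self.latency_corrected,
        )

    def select_channels(self, names: Sequence[str]) -> "EpochSet":
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"channels not present in epochs: {missing}")
        idx = [self.channels.index(n) for n in names]
        return EpochSet(
            data=self.data[:, idx, :],
            fs=self.fs,
            labels=self.labels.copy(),
            blocks=self.blocks.copy(),
            channels=list(names),
            latency_corrected=self.latency_corrected,
        )

    def crop(self, start_s: float, duration_s: float) -> "EpochSet":
        """Half-open crop [start, start + duration) in seconds from epoch start."""
        i0 = int(round(start_s * self.fs))
        n = int(round(duration_s * self.fs))
        if i0 < 0 or i0 + n > self.n_samples:
            raise ValueError("crop window exceeds the epoch extent")
        return EpochSet(
            data=self.data[:, :, i0 : i0 + n],
            fs=self.fs,
            labels=self.labels.copy(),
            blocks=self.blocks.copy(),
            channels=list(self.channels),
            latency_corrected=self.latency_corrected,
        )

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path) -> None:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("blocks", data=self.blocks)
            f.attrs["fs"] = float(self.fs)
            f.attrs["channels"] = [n.encode() for n in self.channels]
            f.attrs["latency_corrected"] = bool(self.latency_corrected)
        sidecar = {
            "fs": float(self.fs),
            "channels": list(self.channels),
            "latency_corrected": bool(self.latency_corrected),
            "n_trials": int(self.n_trials),
            "n_samples": int(self.n_samples),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            for name in ("data", "labels", "blocks"):
                if name not in f:
                    raise ValueError(f"corrupt epoch container: missing /{name}")
            channels = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in f.attrs["channels"]
            ]
            return cls(
                data=f["data"][()],
                fs=float(f.attrs["fs"]),
                labels=f["labels"][()],
                blocks=f["blocks"][()],
                channels=channels,
                latency_corrected=bool(f.attrs["latency_corrected"]),
            )
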
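"""Electrode montages and the four study configurations.

Ships idealized coordinate tables for 256-, 128- and 64-channel caps laid
out on 10-5 system positions, plus the four parieto-occipital decoding
configurations 66/256, 32/128, 21/64 and 9/64 (numerator: electrodes used
for decoding; denominator: total cap channels).  Coordinates are idealized
head-surface positions in centimetres - adequate for interelectrode-distance
summaries and for the synthetic generator's spatial model, not claimed to be
subject-accurate.  The channel lists are plain data files users may replace.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .containers import EpochSet

CONFIG_LABELS = ("66/256", "32/128", "21/64", "9/64")

_CAP_FOR_CONFIG = {"66/256": 256, "32/128": 128, "21/64": 64, "9/64": 64}

BASELINE_9 = ("Pz", "POz", "Oz", "PO3", "PO4", "PO5", "PO6", "O1", "O2")


@dataclass
class Montage:
    """Named electrode set with 3-D head-surface positions in cm."""

    channel_names: list[str]
    positions: np.ndarray  # (n, 3) cm
    config_label: str = ""
    cap_total: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.channel_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    def __len__(self) -> int:
        return len(self.channel_names)

    def position_of(self, name: str) -> np.ndarray:
        return self.positions[self.channel_names.index(name)]

    def take(self, names) -> "Montage":
        missing = [n for n in names if n not in self.channel_names]
        if missing:
            raise KeyError(f"channels not in montage: {missing}")
        idx = [self.channel_names.index(n) for n in names]
        return Montage(
            channel_names=list(names),
            positions=self.positions[idx],
            config_label=self.config_label,
            cap_total=self.cap_total,
        )


def _data_path(name: str):
    return resources.files("ssvepkit.data.montage") / name


def load_cap(cap_total: int) -> Montage:
    """Full idealized cap (256, 128 or 64 channels)."""
    if cap_total not in (256, 128, 64):
        raise ValueError("cap_total must be one of 256, 128, 64")
    with resources.as_file(_data_path(f"cap{cap_total}.csv")) as p:
        df = pd.read_csv(p)
    return Montage(
        channel_names=df["name"].tolist(),
        positions=df[["x_cm", "y_cm", "z_cm"]].to_numpy(),
        config_label=f"cap{cap_total}",
        cap_total=cap_total,
    )


def load_configuration(label: str) -> Montage:
    """One of the four parieto-occipital decoding configurations."""
    if label not in CONFIG_LABELS:
        raise ValueError(
            f"unknown configuration {label!r}; valid labels: {list(CONFIG_LABELS)}"
        )
    cap_total = _CAP_FOR_CONFIG[label]
    cap = load_cap(cap_total)
    fname = "config_" + label.replace("/", "_") + ".txt"
    with resources.as_file(_data_path(fname)) as p:
        names = [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]
    m = cap.take(names)
    m.config_label = label
    m.cap_total = cap_total
    return m


def mean_interelectrode_distance(m: Montage) -> float:
    """Mean over channels of the nearest-neighbour Euclidean distance, cm.

    Euclidean chord distance approximates the geodesic well at typical
    nearest-neighbour separations (< 3 cm on a ~9 cm-radius head).
    """
    if len(m) < 2:
        raise ValueError("need at least 2 channels")
    d = cdist(m.positions, m.positions)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def subset(epochs: EpochSet, m: Montage) -> EpochSet:
    """Channel-slice an epoch set down to a montage, preserving metadata."""
    return epochs.select_channels(m.channel_names)
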
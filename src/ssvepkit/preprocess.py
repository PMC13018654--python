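"""Epoch extraction, resampling and filter-bank decomposition.

Epochs are extracted with a fixed visual-latency offset and a half-open
[start, stop) boundary convention, optionally resampled by polyphase
anti-aliased decimation (integer factors only, e.g. 1000 -> 250 Hz).

The filter bank follows the harmonic-ladder rule: subband m spans
[m * f_min - 2, 90] Hz with f_min = 8 Hz, so five subbands give
[6, 90], [14, 90], [22, 90], [30, 90], [38, 90].  Filters are zero-phase
forward-backward Chebyshev type I bandpasses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import signal

from .containers import EpochSet

__all__ = [
    "FilterBankSpec",
    "build_filterbank",
    "apply_filterbank",
    "extract_epochs",
    "resample_epochs",
    "latency_crop",
]


@dataclass
class FilterBankSpec:
    """Subband edges and filter design for the harmonic filter bank."""

    f_min: float = 8.0  # Hz, lowest stimulus frequency
    n_subbands: int = 5
    f_high: float = 90.0  # Hz, shared upper edge
    order: int = 4
    ripple_db: float = 0.5  # per filtering direction; doubled by filtfilt
    zero_phase: bool = True

    @property
    def bands(self) -> list[tuple[float, float]]:
        return [
            (m * self.f_min - 2.0, self.f_high)
            for m in range(1, self.n_subbands + 1)
        ]

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)

    @classmethod
    def from_json(cls, path) -> "FilterBankSpec":
        with open(path) as f:
            return cls(**json.load(f))


def build_filterbank(spec: FilterBankSpec, fs: float) -> list[np.ndarray]:
    """Second-order-section bandpass operators, one per subband."""
    if spec.f_high >= fs / 2:
        raise ValueError(
            f"upper edge {spec.f_high} Hz requires fs > {2 * spec.f_high} Hz"
        )
    return [
        signal.cheby1(spec.order, spec.ripple_db, [lo, hi], btype="bandpass", fs=fs, output="sos")
        for lo, hi in spec.bands
    ]


def apply_filterbank(
    es: EpochSet, bank: Sequence[np.ndarray], zero_phase: bool = True
) -> list[EpochSet]:
    """Filter every trial through each subband; shapes are preserved.

    Zero-phase filtering (forward-backward with edge padding) keeps the
    SSVEP phase structure intact, which template correlation relies on.
    """
    out = []
    for sos in bank:
        if zero_phase:
            filt = signal.sosfiltfilt(sos, es.data, axis=-1)
        else:
            filt = signal.sosfilt(sos, es.data, axis=-1)
        out.append(
            EpochSet(
                data=filt,
                fs=es.fs,
                labels=es.labels.copy(),
                blocks=es.blocks.copy(),
                channels=list(es.channels),
                latency_corrected=es.latency_corrected,
            )
        )
    return out


def extract_epochs(
    raw: np.ndarray,
    events: Sequence[int],
    *,
    fs_in: float,
    latency: float,
    window: float,
    fs_out: float | None = None,
    channels: Sequence[str] | None = None,
    labels: Sequence[int] | None = None,
    blocks: Sequence[int] | None = None,
) -> EpochSet:
    """Slice epochs [onset + latency, onset + latency + window) from a
    continuous recording and optionally downsample.

    ``events`` are onset sample indices at ``fs_in``.  Resampling uses
    polyphase anti-aliased decimation and requires fs_in / fs_out to be an
    integer.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("raw must be (channels, samples)")
    fs_out = fs_out or fs_in
    ratio = fs_in / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs_in/fs_out must be an integer, got {ratio}")
    ratio = int(round(ratio))
    n_out = int(round(window * fs_out))
    n_in = n_out * ratio
    off = int(round(latency * fs_in))
    epochs = []
    for ev in events:
        start = int(ev) + off
        if start < 0 or start + n_in > raw.shape[1]:
            raise ValueError(
                f"event at sample {ev}: window [{start}, {start + n_in}) "
                f"exceeds the recording of {raw.shape[1]} samples"
            )
        seg = raw[:, start : start + n_in]
        if ratio > 1:
            seg = signal.resample_poly(seg, up=1, down=ratio, axis=-1)
        epochs.append(seg)
    n_trials = len(events)
    return EpochSet(
        data=np.stack(epochs),
        fs=fs_out,
        labels=np.asarray(labels) if labels is not None else np.zeros(n_trials, int),
        blocks=np.asarray(blocks) if blocks is not None else np.zeros(n_trials, int),
        channels=list(channels) if channels is not None else [f"ch{i}" for i in range(raw.shape[0])],
        latency_corrected=True,
    )


def latency_crop(es: EpochSet, latency: float, window: float) -> EpochSet:
    """Apply the visual-latency offset to already-epoched data."""
    out = es.crop(latency, window)
    out.latency_corrected = True
    return out


def resample_epochs(es: EpochSet, fs_out: float) -> EpochSet:
    """Integer-factor polyphase downsampling of an epoch set."""
    ratio = es.fs / fs_out
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs/fs_out must be an integer, got {ratio}")
    ratio = int(round(ratio))
    if ratio == 1:
        return es
    data = signal.resample_poly(es.data, up=1, down=ratio, axis=-1)
    return EpochSet(
        data=data,
        fs=fs_out,
        labels=es.labels.copy(),
        blocks=es.blocks.copy(),
        channels=list(es.channels),
        latency_corrected=es.latency_corrected,
    )
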
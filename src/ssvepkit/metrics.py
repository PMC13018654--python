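"""Performance and signal-quality metrics.

Covers the Wolpaw information transfer rate (bits per selection plus an
actual bits-per-minute and a theoretical bits-per-second rate), the
narrow-band SNR of an SSVEP response (target-frequency amplitude over the
mean of its ten 1-Hz neighbours, in dB), leave-one-block-out cross-validated
accuracy, interchannel Pearson correlations, complex spectrum features after
spatiotemporal filtering, and personalized-configuration selection by actual
ITR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .containers import EpochSet

__all__ = [
    "ITRResult",
    "itr",
    "amplitude_at",
    "amplitude_spectrum_1hz",
    "snr_spectrum",
    "crossvalidate",
    "channel_correlation",
    "complex_feature",
    "select_personalized_config",
]


# --------------------------------------------------------------------- ITR
@dataclass
class ITRResult:
    bits_per_selection: float
    rate: float
    unit: str  # "bpm" (actual) or "bps" (theoretical)
    below_chance: bool = False


def itr_bits(n_targets: int, p: float) -> float:
    """Wolpaw bits per selection for an N-choice task at accuracy P."""
    if n_targets < 2:
        raise ValueError("n_targets must be >= 2")
    if not 0.0 <= p <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    bits = math.log2(n_targets)
    if p > 0.0:
        bits += p * math.log2(p)
    if p < 1.0:
        bits += (1.0 - p) * math.log2((1.0 - p) / (n_targets - 1))
    return bits


def itr(
    n_targets: int,
    p: float,
    stim_s: float,
    cue_s: float = 0.5,
    mode: str = "actual",
) -> ITRResult:
    """Information transfer rate.

    ``actual`` counts stimulation plus cue (gaze-shift) time per selection and
    reports bits per minute; ``theoretical`` counts only stimulation time and
    reports bits per second.
    """
    if mode not in ("actual", "theoretical"):
        raise ValueError("mode must be 'actual' or 'theoretical'")
    if stim_s <= 0 or (mode == "actual" and stim_s + cue_s <= 0):
        raise ValueError("selection time must be positive")
    bits = itr_bits(n_targets, p)
    below = p < 1.0 / n_targets
    if below:
        warnings.warn(
            f"accuracy {p:.3f} is below chance 1/{n_targets}; ITR is not meaningful",
            stacklevel=2,
        )
    if mode == "actual":
        return ITRResult(bits, bits * 60.0 / (stim_s + cue_s), "bpm", below)
    return ITRResult(bits, bits / stim_s, "bps", below)


# --------------------------------------------------------------- SNR (dB)
def dtft_at(x: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Complex discrete-time Fourier transform at arbitrary frequencies (Hz).

    Evaluating the DTFT directly is the continuous-grid limit of zero-padded
    FFT interpolation, so off-grid stimulus frequencies (e.g. 8.2 Hz) are
    handled exactly.  ``x`` may be (n,) or (channels, n).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    t = np.arange(n) / fs
    basis = np.exp(-2j * np.pi * np.outer(np.asarray(freqs, dtype=float), t))
    return (x @ basis.T).squeeze()


def amplitude_at(x: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """Amplitude spectrum at arbitrary frequencies; see :func:`dtft_at`."""
    return np.abs(dtft_at(x, freqs, fs))


def amplitude_spectrum_1hz(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded amplitude spectrum on an exact 1-Hz grid.

    Pads to the next whole-second equivalent (a multiple of ``fs`` samples)
    so the frequency resolution is exactly 1 Hz, then keeps every bin from 0
    to the Nyquist frequency.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[-1]
    nfft = int(math.ceil(n / fs) * fs)
    spec = np.abs(np.fft.rfft(x, n=nfft, axis=-1))
    step = nfft // int(fs)  # bins per Hz; exact by construction
    grid = spec[..., ::step]
    freqs = np.arange(grid.shape[-1], dtype=float)
    return freqs, grid.squeeze()


def snr_spectrum(mean_epoch: np.ndarray, f: float, fs: float) -> np.ndarray:
    """Narrow-band SNR in dB per channel at stimulus frequency ``f``.

    SNR = 20*log10(10*y(f) / sum of y at the ten 1-Hz neighbours), i.e. the
    target-frequency amplitude over the mean amplitude of the 5 bins on each
    side.  ``mean_epoch`` should be trial-averaged data (channels x samples).
    """
    n_side = 5
    if f - n_side <= 0 or f + n_side >= fs / 2:
        raise ValueError(
            f"target frequency {f} Hz too close to 0 or Nyquist for +/-{n_side} Hz neighbours"
        )
    x = np.atleast_2d(mean_epoch)
    freqs = np.concatenate(
        ([f], [f - k for k in range(1, n_side + 1)], [f + k for k in range(1, n_side + 1)])
    )
    amps = np.atleast_2d(amplitude_at(x, freqs, fs))
    target = amps[:, 0]
    noise_sum = amps[:, 1:].sum(axis=1)
    with np.errstate(divide="ignore"):
        out = 20.0 * np.log10(10.0 * target / noise_sum)
    return out if mean_epoch.ndim > 1 else float(out[0])


# ----------------------------------------------------- cross-validation
def crossvalidate(
    subbands: Sequence[EpochSet],
    frequencies: dict[int, float],
    windows: Sequence[float],
    *,
    algorithm: str = "tdca",
    delay_order: int = 4,
    n_components: int = 8,
    n_harmonics_ref: int = 5,
) -> pd.DataFrame:
    """Leave-one-block-out accuracy over a grid of decoding windows.

    ``subbands`` are full-length filter-bank epochs (one EpochSet per
    subband, identical trial metadata).  Every block serves once as the test
    set; the decoder is refit per (window, fold) and test windows crop each
    epoch from its start.  Returns a frame with ``window_s`` and
    ``accuracy`` columns.
    """
    from . import decoder as dec

    if algorithm not in ("tdca", "trca"):
        raise ValueError("algorithm must be 'tdca' or 'trca'")
    first = subbands[0]
    fs = first.fs
    block_ids = np.unique(first.blocks)
    if len(block_ids) < 2:
        raise ValueError("need at least 2 blocks for leave-one-block-out CV")
    label_set = set(np.unique(first.labels))
    rows = []
    for w in windows:
        n_pts = int(round(w * fs))
        fold_acc = []
        for b in block_ids:
            train_mask = first.blocks != b
            train = [es.select_trials(train_mask) for es in subbands]
            test = [es.select_trials(~train_mask) for es in subbands]
            missing = label_set - set(np.unique(train[0].labels))
            if missing:
                raise ValueError(
                    f"classes {sorted(missing)} missing from training folds"
                )
            if algorithm == "tdca":
                model = dec.fit_tdca(
                    train,
                    frequencies,
                    n_pts,
                    delay_order=delay_order,
                    n_components=n_components,
                    n_harmonics_ref=n_harmonics_ref,
                )
                _, _, pred = dec.score_batch(
                    [es.data[:, :, :n_pts] for es in test], model
                )
            else:
                model = dec.fit_trca(train, n_pts)
                _, pred = dec.score_batch_trca(
                    [es.data[:, :, :n_pts] for es in test], model
                )
            fold_acc.append(float(np.mean(pred == test[0].labels)))
        rows.append({"window_s": float(w), "accuracy": float(np.mean(fold_acc))})
    return pd.DataFrame(rows)


# ------------------------------------------------- channel correlations
def channel_correlation(es: EpochSet) -> tuple[np.ndarray, float]:
    """Channel x channel Pearson matrix over concatenated trials.

    Returns the symmetric unit-diagonal matrix and the mean of its
    off-diagonal entries.  Constant channels correlate as 0 (with a warning)
    so degenerate fixtures stay computable.
    """
    x = es.data.transpose(1, 0, 2).reshape(es.n_channels, -1)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples to correlate")
    sd = x.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant channels {list(np.asarray(es.channels)[const])}; "
            "their correlations are reported as 0",
            stacklevel=2,
        )
    xc = x - x.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ xc.T) / denom
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    off = ~np.eye(len(r), dtype=bool)
    return r, float(r[off].mean())


# --------------------------------------------- complex spectrum feature
def complex_feature(es: EpochSet, model, code) -> np.ndarray:
    """One complex number per trial of ``code``: the fundamental-frequency
    bin of the first spatiotemporally filtered component.

    Each trial is delay-embedded, projected onto the model's leading filter
    column (first subband), and Fourier-transformed on a 1-Hz grid; the
    returned values separate fixation points by amplitude and phase.
    """
    from .decoder import delay_embed  # local import to avoid a cycle

    mask = es.labels == code.target_id
    if not mask.any():
        raise ValueError(f"no trials labelled {code.target_id}")
    w = model.filters[0][:, 0]
    n = int(math.ceil(es.n_samples / es.fs) * es.fs)
    step = n // int(es.fs)
    f_idx = int(round(code.frequency)) * step
    out = []
    for x in es.data[mask]:
        z = w @ delay_embed(x, model.delay_order, test_mode=True)
        spec = np.fft.rfft(z, n=n)
        out.append(spec[f_idx])
    return np.asarray(out)


# ------------------------------------- personalized configuration choice
def select_personalized_config(table: pd.DataFrame, cue_s: float = 0.5) -> pd.Series:
    """Pick the (target number, combo, window) cell with the best actual ITR.

    ``table`` needs columns ``n_targets``, ``combo``, ``window_s`` and
    ``accuracy``.  Ties prefer fewer targets, then shorter windows.
    """
    if table.empty:
        raise ValueError("empty accuracy table")
    t = table.copy()
    t["itr_actual_bpm"] = [
        itr(int(r.n_targets), float(r.accuracy), float(r.window_s), cue_s).rate
        for r in t.itertuples()
    ]
    # group near-identical rates (sub-micro-bpm) so ties resolve by the
    # stated preference rather than floating-point noise
    t["_rate_key"] = t["itr_actual_bpm"].round(6)
    t = t.sort_values(
        ["_rate_key", "n_targets", "window_s"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return t.drop(columns="_rate_key").iloc[0]
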
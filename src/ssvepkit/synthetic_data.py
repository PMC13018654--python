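"""Seeded generator of synthetic SSVEP epochs.

The generator reproduces the statistical structure the decoder relies on,
so every downstream stage is testable without the study's recordings:

* a steady-state response at the stimulus fundamental and ``n_harmonics``
  harmonics, delayed by a fixed visual latency and decaying geometrically
  across harmonics;
* a fixation-dependent spatial gain: a right (left) fixation lateralizes the
  harmonic response toward the right (left) hemisphere, a down fixation
  spreads a broad inferior-occipital response, an up fixation concentrates
  the response over superior-parietal sites, and a center fixation produces
  a symmetric medial-occipital topography;
* a smooth fixation-specific phase gradient across the scalp;
* background noise with a 1/f^beta spectrum whose interchannel correlation
  decays with electrode distance, plus uncorrelated sensor noise, scaled so
  the single-trial narrow-band SNR at the best channel matches
  ``target_snr_db``.

Everything is driven by one integer seed; identical configuration and seed
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import EpochSet
from .metrics import amplitude_at
from .montage import Montage
from .paradigm import TargetCode

__all__ = [
    "FixationGain",
    "SimConfig",
    "default_fixation_gain_profile",
    "synth_trial",
    "synth_dataset",
    "realized_snr",
]

# Canonical scalp directions (unit vectors; x right, y anterior, z up).
_OCC = np.array([0.0, -1.0, -0.25])
_OCC_INF = np.array([0.0, -0.9, -0.6])
_PARIETAL = np.array([0.0, -0.55, 0.85])
_RIGHT = np.array([1.0, 0.0, 0.0])
_UP = np.array([0.0, 0.0, 1.0])
_ANT = np.array([0.0, 1.0, 0.0])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class FixationGain:
    """Spatial gain parameters for one fixation position.

    The gain over the scalp is a von-Mises-like blob
    ``amp * exp(kappa * (cos(angle to center) - 1))`` with separate centers
    and concentrations for the fundamental and the harmonics, plus the
    direction of the phase gradient.
    """

    fund_center: tuple[float, float, float]
    fund_kappa: float
    fund_amp: float
    harm_center: tuple[float, float, float]
    harm_kappa: float
    harm_amp: float
    phase_dir: tuple[float, float, float]


def default_fixation_gain_profile() -> dict[str, FixationGain]:
    """Qualitative defaults for the five fixation topography classes."""
    occ, inf_, par = _unit(_OCC), _unit(_OCC_INF), _unit(_PARIETAL)
    r_harm = _unit(_OCC + 0.55 * _RIGHT)
    l_harm = _unit(_OCC - 0.55 * _RIGHT)
    r_fund = _unit(_OCC + 0.18 * _RIGHT)
    l_fund = _unit(_OCC - 0.18 * _RIGHT)
    t = tuple
    return {
        "right": FixationGain(t(r_fund), 9.0, 1.0, t(r_harm), 12.0, 1.2, t(_RIGHT)),
        "left": FixationGain(t(l_fund), 9.0, 1.0, t(l_harm), 12.0, 1.2, t(-_RIGHT)),
        "down": FixationGain(t(inf_), 4.0, 1.2, t(occ), 8.0, 1.0, t(-_UP)),
        "up": FixationGain(t(par), 16.0, 1.0, t(occ), 8.0, 1.0, t(_UP)),
        "center": FixationGain(t(occ), 10.0, 1.0, t(occ), 10.0, 1.0, t(_ANT)),
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    montage: Montage
    code_table: Sequence[TargetCode]
    fs: float = 1000.0  # Hz
    latency: float = 0.140  # s, visual response delay
    n_harmonics: int = 5
    harmonic_decay: float = 0.5  # amplitude ratio between successive harmonics
    amplitude: float = 1.0  # uV-scale base amplitude of the fundamental
    fixation_gain_profile: dict[str, FixationGain] | None = None
    latency_jitter: float = 0.001  # s, per-trial SD of the visual latency
    amplitude_jitter: float = 0.1  # relative per-trial SD of response amplitude
    target_snr_db: float | None = 12.0  # None: deterministic (noise and jitter off)
    noise_exponent: float = 1.0  # beta of the 1/f^beta background
    noise_spatial_scale: float = 3.0  # cm, e-folding of interchannel correlation
    sensor_noise_frac: float = 0.1  # variance fraction of uncorrelated noise
    phase_gradient: float = 0.12  # rad/cm of the channel phase gradient
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixation_gain_profile is None:
            self.fixation_gain_profile = default_fixation_gain_profile()
        if not 0.0 < self.harmonic_decay <= 1.0:
            raise ValueError("harmonic_decay must lie in (0, 1]")
        fmax = max(c.frequency for c in self.code_table)
        if self.n_harmonics * fmax >= self.fs / 2:
            raise ValueError(
                f"n_harmonics * max frequency = {self.n_harmonics * fmax} Hz "
                f"violates the Nyquist limit fs/2 = {self.fs / 2} Hz"
            )


# ----------------------------------------------------------- spatial model
def _blob_gain(montage: Montage, center, kappa: float, amp: float) -> np.ndarray:
    p = montage.positions
    phat = p / np.linalg.norm(p, axis=1, keepdims=True)
    cos = phat @ _unit(np.asarray(center, dtype=float))
    return amp * np.exp(kappa * (cos - 1.0))


def channel_gains(cfg: SimConfig, fixation: str) -> np.ndarray:
    """Per-channel gain for each harmonic, shape (n_harmonics, n_channels)."""
    prof = cfg.fixation_gain_profile[fixation]
    g_fund = _blob_gain(cfg.montage, prof.fund_center, prof.fund_kappa, prof.fund_amp)
    g_harm = _blob_gain(cfg.montage, prof.harm_center, prof.harm_kappa, prof.harm_amp)
    return np.stack([g_fund] + [g_harm] * (cfg.n_harmonics - 1))


def channel_phases(cfg: SimConfig, fixation: str) -> np.ndarray:
    """Smooth per-channel phase offset psi (rad) for one fixation."""
    prof = cfg.fixation_gain_profile[fixation]
    return cfg.phase_gradient * (cfg.montage.positions @ _unit(np.asarray(prof.phase_dir)))


_MIXER_CACHE: dict[tuple, np.ndarray] = {}


def _spatial_mixer(montage: Montage, scale_cm: float) -> np.ndarray:
    """Symmetric square root of the distance-kernel correlation matrix."""
    key = (tuple(montage.channel_names), float(scale_cm), montage.positions.tobytes())
    if key not in _MIXER_CACHE:
        d = np.linalg.norm(
            montage.positions[:, None, :] - montage.positions[None, :, :], axis=-1
        )
        k = np.exp(-d / scale_cm)
        vals, vecs = np.linalg.eigh(k)
        vals = np.clip(vals, 0.0, None)
        _MIXER_CACHE[key] = (vecs * np.sqrt(vals)) @ vecs.T
    return _MIXER_CACHE[key]


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, beta: float) -> np.ndarray:
    """Unit-variance 1/f^beta noise per channel, built in the frequency domain."""
    n_bins = n // 2 + 1
    freqs = np.fft.rfftfreq(n)
    mag = np.zeros(n_bins)
    mag[1:] = freqs[1:] ** (-beta / 2.0)
    z = rng.standard_normal((n_ch, n_bins)) + 1j * rng.standard_normal((n_ch, n_bins))
    x = np.fft.irfft(z * mag, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _signal_part(
    code: TargetCode, duration: float, cfg: SimConfig, latency: float | None = None
) -> np.ndarray:
    n = int(round(duration * cfg.fs))
    if n < 2:
        raise ValueError("duration * fs must be at least 2 samples")
    tau = cfg.latency if latency is None else latency
    t = np.arange(n) / cfg.fs
    gains = channel_gains(cfg, code.fixation)  # (Nh, Nc)
    psi = channel_phases(cfg, code.fixation)  # (Nc,)
    x = np.zeros((len(cfg.montage), n))
    for h in range(1, cfg.n_harmonics + 1):
        a = cfg.amplitude * cfg.harmonic_decay ** (h - 1)
        arg = 2.0 * np.pi * h * code.frequency * (t - tau) + h * code.phase
        x += a * gains[h - 1][:, None] * np.sin(arg[None, :] + psi[:, None])
    return x


def synth_trial(
    code: TargetCode,
    duration: float,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One synthetic trial, channels x samples, in uV.

    Epochs span stimulus time from onset; the evoked component is a pure
    delay by the visual latency, drawn per trial around ``cfg.latency`` with
    SD ``cfg.latency_jitter``, and its amplitude fluctuates log-normally
    across trials (``amplitude_jitter``).  The noise amplitude is calibrated
    per trial so that, at the nominal response amplitude, the narrow-band
    SNR at the strongest channel matches ``cfg.target_snr_db``; with
    ``target_snr_db=None`` the trial is noiseless.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if cfg.target_snr_db is None:
        # noiseless mode: the fully deterministic evoked component, with
        # trial-to-trial jitter disabled as well (used for validation)
        return _signal_part(code, duration, cfg)
    tau = cfg.latency
    if cfg.latency_jitter > 0:
        tau += rng.normal(0.0, cfg.latency_jitter)
    amp = math.exp(rng.normal(0.0, cfg.amplitude_jitter)) if cfg.amplitude_jitter > 0 else 1.0
    sig = _signal_part(code, duration, cfg, latency=tau)
    n_ch, n = sig.shape
    pink = _pink_noise(rng, n_ch, n, cfg.noise_exponent)
    mixer = _spatial_mixer(cfg.montage, cfg.noise_spatial_scale)
    eta = (
        math.sqrt(1.0 - cfg.sensor_noise_frac) * (mixer @ pink)
        + math.sqrt(cfg.sensor_noise_frac) * rng.standard_normal((n_ch, n))
    )
    # noise floor is tied to the nominal amplitude, so amplitude jitter
    # translates into trial-to-trial SNR variation
    sigma = _calibrated_noise_scale(sig, eta, code, cfg)
    if sigma is None:
        return amp * sig
    return amp * sig + sigma * eta


def calibration_channel(cfg: SimConfig, code: TargetCode) -> int:
    """Index of the channel with the strongest fundamental response, where
    the noise scale is calibrated to ``target_snr_db``."""
    return int(np.argmax(channel_gains(cfg, code.fixation)[0]))


def _calibrated_noise_scale(
    sig: np.ndarray, eta: np.ndarray, code: TargetCode, cfg: SimConfig
) -> float | None:
    """Noise scale making the measured narrow-band SNR at the calibration
    channel equal the target exactly for this realization.

    Solves |s_f + sigma * n_f| = R * sigma * mean|n_neighbours| for sigma,
    where s_f and n_f are the complex spectra of signal and noise at the
    fundamental and R = 10^(target/20); the quadratic accounts for the noise
    component inside the target bin itself.
    """
    from .metrics import dtft_at

    calib = calibration_channel(cfg, code)
    f = code.frequency
    s_f = complex(dtft_at(sig[calib], np.array([f]), cfg.fs))
    n_f = complex(dtft_at(eta[calib], np.array([f]), cfg.fs))
    neigh = np.array([f + k for k in range(-5, 6) if k != 0])
    y_noise = float(np.mean(np.abs(dtft_at(eta[calib], neigh, cfg.fs))))
    if y_noise == 0.0:
        return None
    r = 10.0 ** (cfg.target_snr_db / 20.0)
    a = (r * y_noise) ** 2 - abs(n_f) ** 2
    b = (s_f * n_f.conjugate()).real
    if a <= 0.0:  # noise at the target bin anomalously large; simple fallback
        return abs(s_f) / (r * y_noise)
    return (b + math.sqrt(b * b + a * abs(s_f) ** 2)) / a


def synth_dataset(
    n_blocks: int,
    codes: Sequence[TargetCode],
    duration: float,
    cfg: SimConfig,
) -> EpochSet:
    """Blocked dataset: each block traverses every code once in seeded
    shuffled order, mirroring the blocked acquisition design."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if len(codes) == 0:
        raise ValueError("code list must not be empty")
    root = np.random.SeedSequence(cfg.seed)
    block_seqs = root.spawn(n_blocks)
    data, labels, blocks = [], [], []
    for b, bs in enumerate(block_seqs):
        children = bs.spawn(len(codes) + 1)
        order = np.random.default_rng(children[0]).permutation(len(codes))
        for ci in order:
            rng = np.random.default_rng(children[1 + int(ci)])
            data.append(synth_trial(codes[int(ci)], duration, cfg, rng=rng))
            labels.append(codes[int(ci)].target_id)
            blocks.append(b)
    return EpochSet(
        data=np.stack(data),
        fs=cfg.fs,
        labels=np.array(labels),
        blocks=np.array(blocks),
        channels=list(cfg.montage.channel_names),
        latency_corrected=False,
    )


def realized_snr(es: EpochSet, code: TargetCode, channel: str | None = None) -> float:
    """Narrow-band SNR (dB) of the trial-averaged fundamental; the
    calibration check for ``target_snr_db``.

    With ``channel=None`` the channel with the largest fundamental amplitude
    is used (slightly optimistic at low SNR); pass the calibration channel's
    name for an unbiased single-trial check.  Averaging across blocks raises
    the value above the single-trial target by ~10*log10(n_blocks).
    """
    from .metrics import snr_spectrum

    mask = es.labels == code.target_id
    if not mask.any():
        raise ValueError(f"no trials labelled {code.target_id}")
    mean_epoch = es.data[mask].mean(axis=0)
    if channel is None:
        amps = amplitude_at(mean_epoch, np.array([code.frequency]), es.fs)
        best = int(np.argmax(amps))
    else:
        best = es.channels.index(channel)
    return float(snr_spectrum(mean_epoch, code.frequency, es.fs)[best])
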
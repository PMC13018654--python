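"""Confidence-weighted dynamic-window classification.

Instead of a fixed decoding window, the trial is scored at a ladder of
window lengths (0.1..0.5 s by default).  At the k-th window the fused class
features are multiplied by a confidence factor c_k = (k / 50)^2 that grows
with window length, and a label is emitted as soon as the margin between the
best and second-best weighted feature clears a (negative) risk threshold:
emit when Ts > -(rho_max - rho_2max).  If no window satisfies the threshold
the decision from the longest (fallback) window is adopted.

Sweeping the threshold over a grid trades mean output time against accuracy
and hence actual information transfer rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import EpochSet
from .decoder import TDCAModel, score_batch
from .metrics import itr

__all__ = [
    "DynamicConfig",
    "DecisionTrace",
    "dynamic_classify",
    "window_scores",
    "decide_from_scores",
    "sweep_thresholds",
]


@dataclass
class DynamicConfig:
    """Window ladder, confidence weighting and stopping threshold."""

    windows: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5)
    confidence_denominator: int = 50
    threshold: float = -1e-4  # Ts, strictly negative
    n_thresholds: int = 50
    weighted_gap: bool = True  # margin computed on confidence-weighted features

    def __post_init__(self) -> None:
        w = np.asarray(self.windows)
        if not np.all(np.diff(w) > 0):
            raise ValueError("windows must be strictly increasing")
        if self.threshold >= 0:
            raise ValueError("threshold Ts must be strictly negative")

    @property
    def fallback_window(self) -> float:
        return self.windows[-1]

    def confidence(self, k: int) -> float:
        """c_k = (k / denominator)^2 for the 1-based window index k."""
        return (k / self.confidence_denominator) ** 2

    @property
    def threshold_grid(self) -> np.ndarray:
        """Ts_s = -s * 1e-5 / 2 for s = 1..Ns."""
        s = np.arange(1, self.n_thresholds + 1)
        return -s * 1e-5 / 2.0


@dataclass
class DecisionTrace:
    """Per-window weighted features and the emitted decision for one trial."""

    windows: list[float]
    rho_t: list[np.ndarray]  # confidence-weighted features per evaluated window
    gaps: list[float]  # rho_max - rho_2max per evaluated window
    emitted_k: int  # 1-based index of the emission window
    label: int
    output_time: float  # s
    fallback_used: bool


def _models_per_window(
    model: TDCAModel | Sequence[TDCAModel], n_windows: int
) -> list[TDCAModel]:
    if isinstance(model, TDCAModel):
        return [model] * n_windows
    models = list(model)
    if len(models) != n_windows:
        raise ValueError("need one model per window (or a single shared model)")
    return models


def window_scores(
    subband_test: Sequence[EpochSet],
    model: TDCAModel | Sequence[TDCAModel],
    cfg: DynamicConfig,
) -> np.ndarray:
    """Unweighted fused features at every window: (n_windows, N, Nt).

    Accepts a single model (shorter windows are zero-padded to its training
    window) or one model per window length.
    """
    fs = subband_test[0].fs
    models = _models_per_window(model, len(cfg.windows))
    if round(cfg.windows[-1] * fs) > subband_test[0].n_samples:
        raise ValueError("test epochs are shorter than the longest window")
    out = []
    for w, mdl in zip(cfg.windows, models):
        n = int(round(w * fs))
        trials = [es.data[:, :, :n] for es in subband_test]
        rho, _, _ = score_batch(trials, mdl)
        out.append(rho)
    return np.stack(out)


def decide_from_scores(
    rho_windows: np.ndarray, cfg: DynamicConfig, threshold: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the stopping rule to precomputed features.

    ``rho_windows`` is (n_windows, N, Nt).  Returns (labels_idx (N,) as class
    indices, output_time (N,), fallback_used (N,) bool).
    """
    ts = cfg.threshold if threshold is None else threshold
    if ts >= 0:
        raise ValueError("threshold Ts must be strictly negative")
    n_windows, n_trials, _ = rho_windows.shape
    label_idx = np.empty(n_trials, dtype=int)
    out_time = np.empty(n_trials)
    fallback = np.zeros(n_trials, dtype=bool)
    decided = np.zeros(n_trials, dtype=bool)
    for k in range(1, n_windows + 1):
        c_k = cfg.confidence(k)
        rho_t = c_k * rho_windows[k - 1] if cfg.weighted_gap else rho_windows[k - 1]
        part = np.partition(rho_t, -2, axis=1)
        gap = part[:, -1] - part[:, -2]
        emit = (~decided) & (ts > -gap)
        if k == n_windows:
            fallback = (~decided) & ~emit
            emit = ~decided
        if emit.any():
            label_idx[emit] = np.argmax(rho_windows[k - 1][emit], axis=1)
            out_time[emit] = cfg.windows[k - 1]
            decided |= emit
        if decided.all():
            break
    return label_idx, out_time, fallback


def dynamic_classify(
    subband_trial: Sequence[np.ndarray],
    model: TDCAModel | Sequence[TDCAModel],
    cfg: DynamicConfig,
    fs: float,
) -> DecisionTrace:
    """Classify a single trial with the dynamic-window rule.

    ``subband_trial`` holds one (Nc, Np) array per subband covering at least
    the longest window.
    """
    models = _models_per_window(model, len(cfg.windows))
    n_full = int(round(cfg.windows[-1] * fs))
    if subband_trial[0].shape[-1] < n_full:
        raise ValueError("trial data shorter than the longest window")
    rho_t_list, gaps = [], []
    emitted_k, label, fallback = None, None, False
    for k, (w, mdl) in enumerate(zip(cfg.windows, models), start=1):
        n = int(round(w * fs))
        trials = [x[None, :, :n] for x in subband_trial]
        rho, _, _ = score_batch(trials, mdl)
        rho = rho[0]
        rho_t = cfg.confidence(k) * rho if cfg.weighted_gap else rho
        top2 = np.partition(rho_t, -2)[-2:]
        gap = float(top2[1] - top2[0])
        rho_t_list.append(cfg.confidence(k) * rho)
        gaps.append(gap)
        if cfg.threshold > -gap:
            emitted_k = k
            label = int(mdl.class_list[np.argmax(rho)])
            break
    if emitted_k is None:
        emitted_k = len(cfg.windows)
        fallback = True
        mdl = models[-1]
        label = int(mdl.class_list[np.argmax(rho_t_list[-1])])
    return DecisionTrace(
        windows=list(cfg.windows[:emitted_k]),
        rho_t=rho_t_list,
        gaps=gaps,
        emitted_k=emitted_k,
        label=label,
        output_time=cfg.windows[emitted_k - 1],
        fallback_used=fallback,
    )


def sweep_thresholds(
    subband_test: Sequence[EpochSet],
    model: TDCAModel | Sequence[TDCAModel],
    cfg: DynamicConfig,
    *,
    cue_s: float = 0.5,
) -> pd.DataFrame:
    """Mean output time, accuracy and actual ITR at every grid threshold.

    Features are computed once per window and the stopping rule is re-applied
    per threshold.  Columns: threshold, mean_time_s, accuracy,
    actual_itr_bpm.
    """
    grid = cfg.threshold_grid
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    rho_windows = window_scores(subband_test, model, cfg)
    models = _models_per_window(model, len(cfg.windows))
    class_list = models[0].class_list
    true = subband_test[0].labels
    n_targets = len(class_list)
    rows = []
    for ts in grid:
        idx, times, _ = decide_from_scores(rho_windows, cfg, threshold=float(ts))
        labels = class_list[idx]
        acc = float(np.mean(labels == true))
        mean_t = float(np.mean(times))
        rate = itr(n_targets, acc, mean_t, cue_s).rate if acc >= 1.0 / n_targets else 0.0
        rows.append(
            {
                "threshold": float(ts),
                "mean_time_s": mean_t,
                "accuracy": acc,
                "actual_itr_bpm": rate,
            }
        )
    return pd.DataFrame(rows)
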
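"""End-to-end helpers tying paradigm, simulation, preprocessing and decoding.

The canonical processing chain mirrors the study pipeline: epochs are
extracted with a 140-ms visual-latency offset, downsampled to 250 Hz,
decomposed by the harmonic filter bank, and decoded with filter-bank TDCA
under leave-one-block-out cross-validation.  Decoding windows always crop
the filtered epoch from its start; training epochs keep ``delay_order``
extra samples for the delay embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import decoder, metrics, montage as montage_mod, paradigm, preprocess
from .containers import EpochSet
from .synthetic_data import SimConfig, synth_dataset

__all__ = [
    "build_codes",
    "simulate_dataset",
    "prepare_subbands",
    "frequency_map",
    "fit_window_models",
    "evaluate_configurations",
]

FS_DECODE = 250.0  # Hz after downsampling
LATENCY_S = 0.140


def build_codes(n_fixations: int, combo_label: int = 1) -> list[paradigm.TargetCode]:
    """Code table for one row of the fixation-combination table."""
    combos = paradigm.enumerate_fixation_combos(n_fixations)
    by_label = {c.combo_label: c for c in combos}
    if combo_label not in by_label:
        raise ValueError(
            f"combo_label {combo_label} invalid for {n_fixations} fixations; "
            f"valid: {sorted(by_label)}"
        )
    return paradigm.build_code_table(n_fixations, by_label[combo_label])


def frequency_map(codes: Sequence[paradigm.TargetCode]) -> dict[int, float]:
    return {c.target_id: c.frequency for c in codes}


def simulate_dataset(
    codes: Sequence[paradigm.TargetCode],
    *,
    montage_label: str = "66/256",
    n_blocks: int = 3,
    duration: float = 0.8,
    seed: int = 0,
    fs: float = 1000.0,
    target_snr_db: float | None = 12.0,
    **sim_kwargs,
) -> EpochSet:
    """Generate a blocked synthetic dataset on a study configuration."""
    m = montage_mod.load_configuration(montage_label)
    cfg = SimConfig(
        montage=m,
        code_table=list(codes),
        fs=fs,
        seed=seed,
        target_snr_db=target_snr_db,
        **sim_kwargs,
    )
    return synth_dataset(n_blocks, codes, duration, cfg)


def prepare_subbands(
    es: EpochSet,
    window_s: float,
    *,
    latency: float = LATENCY_S,
    fs_out: float = FS_DECODE,
    delay_order: int = 4,
    bank_spec: preprocess.FilterBankSpec | None = None,
) -> list[EpochSet]:
    """Latency-crop, downsample and filter-bank an epoch set.

    The retained span is ``window_s`` plus ``delay_order`` extra samples (at
    the output rate) so TDCA training windows up to ``window_s`` are valid.
    """
    if not es.latency_corrected:
        keep = window_s + delay_order / fs_out
        es = preprocess.latency_crop(es, latency, keep)
    es = preprocess.resample_epochs(es, fs_out)
    spec = bank_spec or preprocess.FilterBankSpec()
    bank = preprocess.build_filterbank(spec, fs_out)
    return preprocess.apply_filterbank(es, bank)


def fit_window_models(
    subbands_train: Sequence[EpochSet],
    frequencies: dict[int, float],
    windows: Sequence[float],
    **tdca_kwargs,
) -> list[decoder.TDCAModel]:
    """One TDCA model per decoding window (used by dynamic stopping)."""
    fs = subbands_train[0].fs
    return [
        decoder.fit_tdca(subbands_train, frequencies, int(round(w * fs)), **tdca_kwargs)
        for w in windows
    ]


def evaluate_configurations(
    es: EpochSet,
    codes: Sequence[paradigm.TargetCode],
    windows: Sequence[float],
    *,
    config_labels: Sequence[str] = montage_mod.CONFIG_LABELS,
    algorithm: str = "tdca",
    cue_s: float = 0.5,
    combo_label: int | str = "",
    **prep_kwargs,
) -> pd.DataFrame:
    """Cross-validated accuracy and ITR per (configuration, window).

    ``es`` must cover the union of the configurations' channels (generate it
    on the 66/256 montage); each configuration is a channel subset.
    """
    freqs = frequency_map(codes)
    n_targets = len(codes)
    rows = []
    for label in config_labels:
        m = montage_mod.load_configuration(label)
        sub = montage_mod.subset(es, m)
        subbands = prepare_subbands(sub, max(windows), **prep_kwargs)
        acc = metrics.crossvalidate(subbands, freqs, windows, algorithm=algorithm)
        for r in acc.itertuples():
            act = metrics.itr(n_targets, r.accuracy, r.window_s, cue_s, "actual")
            theo = metrics.itr(n_targets, r.accuracy, r.window_s, mode="theoretical")
            rows.append(
                {
                    "config": label,
                    "n_targets": n_targets,
                    "combo": combo_label,
                    "window_s": r.window_s,
                    "accuracy": r.accuracy,
                    "itr_actual_bpm": act.rate,
                    "itr_theoretical_bps": theo.rate,
                }
            )
    return pd.DataFrame(rows)
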
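"""Frequency-phase-space stimulus coding.

A 5 x 8 matrix of luminance-modulated square patches ("flickers") carries a
joint frequency-phase code: frequencies run from 8 to 15.8 Hz in 0.2-Hz steps
and initial phases from 0 in 0.35*pi steps, assigned in traversal order down
each column and then across columns.  Each flicker additionally hosts up to
five fixation points (right, down, left, up, center); the fixation position
relative to the flicker center is the spatial code dimension, multiplying the
command set up to 40 flickers x 5 fixations = 200 targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FIXATIONS = ("right", "down", "left", "up", "center")

F_MIN_HZ = 8.0
F_STEP_HZ = 0.2
PHASE_STEP_RAD = 0.35 * math.pi
N_FLICKERS = 40

__all__ = [
    "FIXATIONS",
    "TargetCode",
    "StimulusLayout",
    "FixationCombo",
    "enumerate_fixation_combos",
    "build_code_table",
    "stimulus_waveform",
    "layout_geometry",
    "code_table_to_csv",
    "code_table_from_csv",
]


@dataclass(frozen=True)
class TargetCode:
    """One selectable command: a flicker (frequency, phase) plus a fixation."""

    flicker_index: int  # 1..40, traversal order of the 5x8 grid
    frequency: float  # Hz
    phase: float  # rad in [0, 2*pi)
    fixation: str
    target_id: int

    def __post_init__(self) -> None:
        if not 1 <= self.flicker_index <= N_FLICKERS:
            raise ValueError(f"flicker_index must be in 1..{N_FLICKERS}")
        if self.fixation not in FIXATIONS:
            raise ValueError(
                f"unknown fixation {self.fixation!r}; allowed: {FIXATIONS}"
            )


def flicker_frequency(flicker_index: int) -> float:
    return F_MIN_HZ + F_STEP_HZ * (flicker_index - 1)


def flicker_phase(flicker_index: int) -> float:
    return (PHASE_STEP_RAD * (flicker_index - 1)) % (2.0 * math.pi)


@dataclass
class StimulusLayout:
    """Geometry of the on-screen stimulus array, in pixels unless noted."""

    grid_rows: int = 5
    grid_cols: int = 8
    flicker_edge: int = 144
    flicker_gap: int = 50
    fixation_offset: int = 36  # = round(0.25 * flicker_edge)
    fixation_size_deg: float = 0.23
    flicker_size_deg: float = 3.3
    screen: tuple[int, int] = (1920, 1080)
    refresh: float = 240.0  # Hz
    viewing_distance_cm: float = 70.0

    def validate(self) -> None:
        if self.fixation_offset != round(0.25 * self.flicker_edge):
            raise ValueError("fixation_offset must equal round(0.25 * flicker_edge)")
        w = self.grid_cols * self.flicker_edge + (self.grid_cols - 1) * self.flicker_gap
        h = self.grid_rows * self.flicker_edge + (self.grid_rows - 1) * self.flicker_gap
        if w > self.screen[0] or h > self.screen[1]:
            raise ValueError("stimulus array does not fit on the screen")


@dataclass(frozen=True)
class FixationCombo:
    """A row of the fixation-combination table for one target count."""

    n_fixations: int
    members: tuple[str, ...]
    combo_label: int

    def __post_init__(self) -> None:
        if len(self.members) != self.n_fixations:
            raise ValueError("len(members) must equal n_fixations")
        for m in self.members:
            if m not in FIXATIONS:
                raise ValueError(f"unknown fixation {m!r}; allowed: {FIXATIONS}")


# Fixation combinations for 1..5 fixation points, in published label order.
_COMBO_TABLE: dict[int, tuple[tuple[str, ...], ...]] = {
    1: (("right",), ("down",), ("left",), ("up",), ("center",)),
    2: (
        ("right", "down"),
        ("right", "left"),
        ("right", "up"),
        ("right", "center"),
        ("down", "left"),
        ("down", "up"),
        ("down", "center"),
        ("left", "up"),
        ("left", "center"),
        ("up", "center"),
    ),
    3: (
        ("left", "up", "center"),
        ("down", "up", "center"),
        ("down", "left", "center"),
        ("down", "left", "up"),
        ("right", "up", "center"),
        ("right", "left", "center"),
        ("right", "left", "up"),
        ("right", "down", "center"),
        ("right", "down", "up"),
        ("right", "down", "left"),
    ),
    4: (
        ("right", "down", "left", "up"),
        ("right", "down", "left", "center"),
        ("right", "down", "up", "center"),
        ("right", "left", "up", "center"),
        ("down", "left", "up", "center"),
    ),
    5: (("right", "down", "left", "up", "center"),),
}


def enumerate_fixation_combos(n_fixations: int) -> list[FixationCombo]:
    """All fixation combinations for a given number of fixation points.

    The returned combos follow the published enumeration: for n points there
    are 5, 10, 10, 5 and 1 combinations respectively, labelled from 1.
    """
    if not 1 <= n_fixations <= 5:
        raise ValueError("n_fixations must be in 1..5")
    return [
        FixationCombo(n_fixations, members, label)
        for label, members in enumerate(_COMBO_TABLE[n_fixations], start=1)
    ]


def build_code_table(n_fixations: int, combo: FixationCombo) -> list[TargetCode]:
    """Code table for one fixation combination: 40 flickers x n fixations.

    Target ids are assigned contiguously from 1, flicker-major then fixation
    in combo order, so the 40-class label space nests inside larger ones.
    """
    if combo.n_fixations != n_fixations:
        raise ValueError("combo.n_fixations does not match n_fixations")
    codes = []
    tid = 1
    for fi in range(1, N_FLICKERS + 1):
        for fx in combo.members:
            codes.append(
                TargetCode(
                    flicker_index=fi,
                    frequency=flicker_frequency(fi),
                    phase=flicker_phase(fi),
                    fixation=fx,
                    target_id=tid,
                )
            )
            tid += 1
    return codes


def stimulus_waveform(
    code: TargetCode, duration: float, refresh: float = 240.0
) -> np.ndarray:
    """Per-frame luminance in [0, 1] by sampled sinusoidal stimulation.

    s[n] = 0.5 * (1 + sin(2*pi*f*n/refresh + phi)), evaluated at frame starts.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if refresh <= 2.0 * code.frequency:
        raise ValueError(
            f"refresh rate {refresh} Hz must exceed twice the stimulus "
            f"frequency {code.frequency} Hz (aliasing)"
        )
    n = np.arange(round(duration * refresh))
    return 0.5 * (1.0 + np.sin(2.0 * math.pi * code.frequency * n / refresh + code.phase))


_FIXATION_OFFSET_DIR = {
    "right": (1, 0),
    "down": (0, 1),  # screen y grows downward
    "left": (-1, 0),
    "up": (0, -1),
    "center": (0, 0),
}


def layout_geometry(layout: StimulusLayout | None = None) -> pd.DataFrame:
    """Pixel coordinates of flicker centers and their five fixation points.

    The array is centered on the screen.  Flicker index runs down each column
    and then across columns.  Returns one row per (flicker, fixation) with
    columns flicker_index, row, col, center_x, center_y, fixation, fix_x,
    fix_y.
    """
    layout = layout or StimulusLayout()
    layout.validate()
    pitch = layout.flicker_edge + layout.flicker_gap
    total_w = layout.grid_cols * layout.flicker_edge + (layout.grid_cols - 1) * layout.flicker_gap
    total_h = layout.grid_rows * layout.flicker_edge + (layout.grid_rows - 1) * layout.flicker_gap
    x0 = (layout.screen[0] - total_w) / 2 + layout.flicker_edge / 2
    y0 = (layout.screen[1] - total_h) / 2 + layout.flicker_edge / 2
    rows = []
    for col in range(layout.grid_cols):
        for row in range(layout.grid_rows):
            fi = col * layout.grid_rows + row + 1
            cx, cy = x0 + col * pitch, y0 + row * pitch
            for fx in FIXATIONS:
                dx, dy = _FIXATION_OFFSET_DIR[fx]
                rows.append(
                    {
                        "flicker_index": fi,
                        "row": row,
                        "col": col,
                        "center_x": cx,
                        "center_y": cy,
                        "fixation": fx,
                        "fix_x": cx + dx * layout.fixation_offset,
                        "fix_y": cy + dy * layout.fixation_offset,
                    }
                )
    return pd.DataFrame(rows)


def code_table_to_csv(codes: Sequence[TargetCode], path) -> None:
    df = pd.DataFrame(
        {
            "target_id": [c.target_id for c in codes],
            "flicker_index": [c.flicker_index for c in codes],
            "frequency_hz": [c.frequency for c in codes],
            "phase_rad": [c.phase for c in codes],
            "fixation": [c.fixation for c in codes],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def code_table_from_csv(path) -> list[TargetCode]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        TargetCode(
            flicker_index=int(r.flicker_index),
            frequency=float(r.frequency_hz),
            phase=float(r.phase_rad),
            fixation=str(r.fixation),
            target_id=int(r.target_id),
        )
        for r in df.itertuples()
    ]
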
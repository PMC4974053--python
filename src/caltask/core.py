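"""Shared containers and the trial time-grid convention.

All trial-aligned arrays use a 5 Hz grid with t = 0 at stimulus onset and a
1 s pre-stimulus baseline window [-1, 0).  Epoch boundaries (stimulus off,
spout in/out) are stored per trial in the trial table, so trials of
different delay share one time axis and simply place their response epoch
at different times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: trial table column order used by every reader/writer in the package
TRIAL_COLUMNS = [
    "trial", "stimulus", "delay_s", "licked", "outcome",
    "laser_on", "laser_epoch",
    "t_stim_on", "t_stim_off", "t_spout_in", "t_spout_out",
]

OUTCOMES = ("hit", "miss", "CR", "FA")


def outcome_of(stimulus: str, licked: bool) -> str:
    """Map (stimulus, lick) to the go/no-go contingency-table outcome."""
    if stimulus == "target":
        return "hit" if licked else "miss"
    return "FA" if licked else "CR"


def time_grid(pre_dur: float, post_dur: float, frame_rate: float) -> np.ndarray:
    """Sample times in seconds, stimulus onset at t=0, baseline in [-pre, 0)."""
    dt = 1.0 / frame_rate
    n_pre = int(round(pre_dur * frame_rate))
    n_post = int(round(post_dur * frame_rate))
    return (np.arange(-n_pre, n_post) * dt).round(10)


@dataclass
class Movie:
    """Registered or raw imaging movie for one plane."""

    frames: np.ndarray          # T x Y x X, nonnegative
    frame_rate: float = 5.0     # Hz
    pixel_size: float = 1.0     # um / px
    plane: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be T x Y x X with T >= 2")
        if not np.all(np.isfinite(self.frames)) or self.frames.min() < 0:
            raise ValueError("movie intensities must be finite and >= 0")


@dataclass
class TrialAlignedTraces:
    """Neuron x trial x time ΔF/F tensor plus the matching trial table.

    ``dff`` is the neuropil-corrected tensor used for all analyses; ``raw_dff``
    (uncorrected) is kept alongside because the response-significance
    criterion must hold on both.
    """

    dff: np.ndarray                     # n_neurons x n_trials x n_time
    time_s: np.ndarray                  # shared time axis, t=0 at stim onset
    table: pd.DataFrame                 # one row per trial
    raw_dff: Optional[np.ndarray] = None
    baseline_window: tuple[float, float] = (-1.0, 0.0)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.dff.ndim != 3:
            raise ValueError("dff must be neuron x trial x time")
        if self.dff.shape[1] != len(self.table):
            raise ValueError("trial axis does not match trial table")
        if self.dff.shape[2] != self.time_s.size:
            raise ValueError("time axis does not match time grid")

    @property
    def n_neurons(self) -> int:
        return self.dff.shape[0]

    @property
    def raw(self) -> np.ndarray:
        return self.dff if self.raw_dff is None else self.raw_dff

    def baseline_mask(self) -> np.ndarray:
        lo, hi = self.baseline_window
        return (self.time_s >= lo) & (self.time_s < hi)


@dataclass
class GroundTruth:
    """Bookkeeping attached to synthetic outputs for recovery tests."""

    archetype: Optional[np.ndarray] = None        # per-neuron label
    preferred: Optional[np.ndarray] = None        # per-neuron trial type
    amplitude: Optional[np.ndarray] = None        # peak ΔF/F on preferred trials
    selectivity: Optional[np.ndarray] = None      # non-pref / pref response ratio
    onset_latency: Optional[np.ndarray] = None    # s from stimulus onset
    region: Optional[str] = None
    masks: Optional[np.ndarray] = None            # labeled-int image (movies)
    shifts: Optional[np.ndarray] = None           # per-frame (dy, dx) applied
    frame_flags: Optional[dict] = None            # movement-injected frames
    extra: dict = field(default_factory=dict)
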
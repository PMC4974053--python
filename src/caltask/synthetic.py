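"""Synthetic sessions, ΔF/F tensors, imaging movies and behavior-camera frames.

The generator emulates a memory-guided go/no-go visual task: a 2 s drifting
grating (target or non-target), a randomized 0/3/6 s delay, then a 1.5 s
response window during which a lick spout is available.  Neurons belong to
one of six response archetypes (four enhanced, two suppressed), and their
fluorescence follows slow GCaMP6s-like kinetics (half-decay > 1 s).  Every
generator is deterministic given (config, seed); per-neuron substreams are
spawned from the single seed so adding neurons does not perturb earlier ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GroundTruth,
    Movie,
    TrialAlignedTraces,
    TRIAL_COLUMNS,
    outcome_of,
    time_grid,
)

ARCHETYPES = (
    "StimOnly", "StimResp", "Delay", "RespOnly",
    "SuppDelayEarly", "SuppDelayLate",
)
SUPPRESSED = ("SuppDelayEarly", "SuppDelayLate")

#: default archetype mixtures per region, emulating the qualitative regional
#: gradient (visual cortex dominated by stimulus-locked cells, frontal motor
#: cortex by delay/response cells).  These are package defaults, not
#: measured proportions.
REGION_MIXTURES: dict[str, dict[str, float]] = {
    "V1": {"StimOnly": 0.35, "StimResp": 0.25, "Delay": 0.05,
           "RespOnly": 0.10, "SuppDelayEarly": 0.15, "SuppDelayLate": 0.10},
    "PPC": {"StimOnly": 0.15, "StimResp": 0.25, "Delay": 0.15,
            "RespOnly": 0.20, "SuppDelayEarly": 0.15, "SuppDelayLate": 0.10},
    "fMC": {"StimOnly": 0.05, "StimResp": 0.15, "Delay": 0.25,
            "RespOnly": 0.30, "SuppDelayEarly": 0.10, "SuppDelayLate": 0.15},
}


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# session / trial table
# ---------------------------------------------------------------------------

@dataclass
class SessionConfig:
    """Parameters of one behavioral session.

    ``hit_rate`` and ``fa_rate`` may be scalars or per-delay mappings; they
    set the probability of licking on target and non-target trials.
    """

    n_trials: int = 300
    delay_set: tuple[float, ...] = (0.0, 3.0, 6.0)
    stim_dur: float = 2.0
    resp_dur: float = 1.5
    pre_dur: float = 1.0
    post_dur: float = 2.5
    iti_dur: float = 3.0
    p_target: float = 0.5
    hit_rate: float | Mapping[float, float] = 0.9
    fa_rate: float | Mapping[float, float] = 0.2
    frame_rate: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ConfigError("n_trials must be >= 1")
        if len(self.delay_set) == 0:
            raise ConfigError("delay_set must be nonempty")
        if any(d < 0 for d in self.delay_set):
            raise ConfigError("delays must be nonnegative")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        for name in ("p_target",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("hit_rate", "fa_rate"):
            for v in self._rate_values(getattr(self, name)):
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{name} values must be in [0, 1]")

    @staticmethod
    def _rate_values(rate) -> list[float]:
        if isinstance(rate, Mapping):
            return list(rate.values())
        return [float(rate)]

    def rate_for(self, which: str, delay: float) -> float:
        rate = self.hit_rate if which == "hit" else self.fa_rate
        if isinstance(rate, Mapping):
            return float(rate[delay])
        return float(rate)


def generate_session(config: SessionConfig) -> pd.DataFrame:
    """Draw a trial table: stimulus, delay, lick and outcome per trial.

    Stimuli are target with probability ``p_target``; delays are drawn
    uniformly from ``delay_set`` (randomly interleaved).  Licking is Bernoulli
    with the configured hit/false-alarm rate for the trial's delay; outcomes
    follow the go/no-go contingency table.  Epoch times are trial-relative
    with stimulus onset at t=0.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_trials
    is_target = rng.random(n) < config.p_target
    delays = np.asarray(config.delay_set, dtype=float)[
        rng.integers(0, len(config.delay_set), size=n)
    ]
    rows = []
    for i in range(n):
        stim = "target" if is_target[i] else "nontarget"
        p_lick = config.rate_for("hit" if is_target[i] else "fa", delays[i])
        licked = bool(rng.random() < p_lick)
        t_spout_in = config.stim_dur + delays[i]
        rows.append({
            "trial": i,
            "stimulus": stim,
            "delay_s": delays[i],
            "licked": licked,
            "outcome": outcome_of(stim, licked),
            "laser_on": False,
            "laser_epoch": "",
            "t_stim_on": 0.0,
            "t_stim_off": config.stim_dur,
            "t_spout_in": t_spout_in,
            "t_spout_out": t_spout_in + config.resp_dur,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def add_laser_trials(
    table: pd.DataFrame,
    epoch: str,
    p_laser: float = 0.5,
    lick_rates_on: Optional[tuple[float, float]] = None,
    seed: int = 0,
    delay: Optional[float] = None,
) -> pd.DataFrame:
    """Mark a random subset of trials as laser-ON for a photoinhibition epoch.

    If ``lick_rates_on`` = (hit_rate, fa_rate) is given, licks and outcomes on
    laser trials are redrawn with those rates, emulating an inhibition effect.
    ``delay`` restricts laser trials to one delay condition (as when only the
    longest delay is photoinhibited).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = table.copy()
    eligible = np.ones(len(out), dtype=bool)
    if delay is not None:
        eligible &= out["delay_s"].to_numpy() == delay
    on = eligible & (rng.random(len(out)) < p_laser)
    out.loc[on, "laser_on"] = True
    out.loc[on, "laser_epoch"] = epoch
    if lick_rates_on is not None:
        hit_on, fa_on = lick_rates_on
        for i in np.flatnonzero(on):
            p = hit_on if out.at[i, "stimulus"] == "target" else fa_on
            licked = bool(rng.random() < p)
            out.at[i, "licked"] = licked
            out.at[i, "outcome"] = outcome_of(out.at[i, "stimulus"], licked)
    return out


# ---------------------------------------------------------------------------
# archetype kernels and trace tensors
# ---------------------------------------------------------------------------

@dataclass
class ArchetypeSpec:
    """One response archetype: drive epochs plus indicator kinetics.

    The kernel is a unit-peak template per delay condition: an epoch-locked
    boxcar drive convolved with a causal exponential whose half-decay time
    emulates GCaMP6s (> 1 s).  Suppressed archetypes have nonpositive
    kernels.
    """

    name: str
    sign: str = "enhanced"
    decay_half_time: float = 1.2    # s; tau = t_half / ln 2
    amplitude_dist: Optional[Callable[[np.random.Generator], float]] = None
    selectivity_dist: Optional[Callable[[np.random.Generator], float]] = None

    def __post_init__(self) -> None:
        if self.name not in ARCHETYPES:
            raise ConfigError(f"unknown archetype {self.name!r}")
        if self.name in SUPPRESSED:
            self.sign = "suppressed"
        if self.decay_half_time <= 1.0:
            raise ConfigError("decay_half_time must exceed 1 s")

    def drive_window(self, delay: float, stim_dur: float = 2.0,
                     resp_dur: float = 1.5) -> tuple[float, float]:
        """(start, stop) of the boxcar drive, in s from stimulus onset."""
        spout_in = stim_dur + delay
        if self.name == "StimOnly":
            return 0.0, stim_dur
        if self.name == "StimResp":
            # two epochs; handled specially in kernel()
            return 0.0, spout_in + resp_dur
        if self.name == "Delay":
            return 0.0, spout_in
        if self.name == "RespOnly":
            return spout_in, spout_in + resp_dur
        if self.name == "SuppDelayEarly":
            return 0.0, stim_dur + delay / 2.0
        # SuppDelayLate
        return stim_dur + delay / 2.0, spout_in + resp_dur

    def kernel(self, time_s: np.ndarray, delay: float,
               stim_dur: float = 2.0, resp_dur: float = 1.5) -> np.ndarray:
        """Unit-peak time course for one delay condition on ``time_s``."""
        dt = float(np.median(np.diff(time_s)))
        spout_in = stim_dur + delay
        drive = np.zeros_like(time_s)
        if self.name == "StimResp":
            drive[(time_s >= 0) & (time_s < stim_dur)] = 1.0
            drive[(time_s >= spout_in) & (time_s < spout_in + resp_dur)] = 1.0
        else:
            a, b = self.drive_window(delay, stim_dur, resp_dur)
            drive[(time_s >= a) & (time_s < b)] = 1.0
        tau = self.decay_half_time / np.log(2.0)
        n_k = int(np.ceil(6.0 * tau / dt))
        decay = np.exp(-np.arange(n_k) * dt / tau)
        out = np.convolve(drive, decay)[: time_s.size]
        peak = out.max()
        if peak > 0:
            out = out / peak
        if self.sign == "suppressed":
            out = -out
        return out

    def onset_time(self, delay: float, stim_dur: float = 2.0,
                   resp_dur: float = 1.5) -> float:
        if self.name == "StimResp":
            return 0.0
        return self.drive_window(delay, stim_dur, resp_dur)[0]


def default_archetypes(decay_half_time: float = 1.2) -> dict[str, ArchetypeSpec]:
    return {name: ArchetypeSpec(name, decay_half_time=decay_half_time)
            for name in ARCHETYPES}


def _default_amplitude(rng: np.random.Generator) -> float:
    # lognormal peak ΔF/F, median 0.5 — typical of strong GCaMP6s transients
    return float(rng.lognormal(mean=np.log(0.5), sigma=0.4))


def _default_selectivity(rng: np.random.Generator) -> float:
    # non-preferred / preferred response ratio; Beta(1.2, 2.4) leans selective
    return float(rng.beta(1.2, 2.4))


def generate_traces(
    table: pd.DataFrame,
    mixture: Mapping[str, float],
    n_neurons: int,
    noise_sd: float = 0.1,
    seed: int = 0,
    frame_rate: float = 5.0,
    pre_dur: float = 1.0,
    post_dur: float = 2.5,
    decay_half_time: float = 1.2,
    archetypes: Optional[Mapping[str, ArchetypeSpec]] = None,
    selectivity_on: str = "stimulus",
    region: Optional[str] = None,
    make_raw: bool = True,
) -> tuple[TrialAlignedTraces, GroundTruth]:
    """Render a neuron x trial x time ΔF/F tensor from archetype kernels.

    Each neuron draws an archetype from ``mixture``, a preferred trial type,
    a peak amplitude and a selectivity ratio; its noiseless expectation on a
    trial is ``amplitude * kernel(delay)`` when the trial matches its
    preference and ``amplitude * ratio * kernel(delay)`` otherwise.
    Additive i.i.d. Gaussian noise of ``noise_sd`` is applied; with
    ``make_raw`` an uncorrected tensor with an independent noise draw (same
    expectation) is attached as ``raw_dff``.

    ``selectivity_on`` chooses whether preference is over the stimulus class
    (target/non-target, the default) or over the animal's choice (lick /
    no-lick), the latter for constructing choice-coding populations.
    """
    probs = np.array([mixture.get(a, 0.0) for a in ARCHETYPES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ConfigError("archetype mixture must sum to 1")
    if n_neurons < 1:
        raise ConfigError("n_neurons must be >= 1")
    if selectivity_on not in ("stimulus", "choice"):
        raise ConfigError("selectivity_on must be 'stimulus' or 'choice'")
    specs = dict(archetypes) if archetypes is not None else \
        default_archetypes(decay_half_time)

    delays = table["delay_s"].to_numpy(dtype=float)
    stim_dur = float((table["t_stim_off"] - table["t_stim_on"]).iloc[0])
    resp_dur = float((table["t_spout_out"] - table["t_spout_in"]).iloc[0])
    # shared axis spans the longest trial plus a post-trial tail
    t = time_grid(pre_dur,
                  stim_dur + delays.max() + resp_dur + post_dur, frame_rate)
    if selectivity_on == "stimulus":
        trial_class = np.where(table["stimulus"] == "target",
                               "target", "nontarget")
        classes = ("target", "nontarget")
    else:
        trial_class = np.where(table["licked"], "lick", "nolick")
        classes = ("lick", "nolick")

    ss = np.random.SeedSequence(seed)
    assign_rng = np.random.default_rng(ss.spawn(1)[0])
    neuron_seeds = np.random.SeedSequence(entropy=ss.entropy,
                                          spawn_key=(1,)).spawn(n_neurons)
    labels = assign_rng.choice(ARCHETYPES, size=n_neurons, p=probs)

    # kernels per (archetype, delay) — shared across neurons
    uniq_delays = np.unique(delays)
    kernels = {
        (a, d): specs[a].kernel(t, d, stim_dur, resp_dur)
        for a in ARCHETYPES for d in uniq_delays
    }

    n_trials, n_time = len(table), t.size
    dff = np.empty((n_neurons, n_trials, n_time))
    raw = np.empty_like(dff) if make_raw else None
    preferred = np.empty(n_neurons, dtype=object)
    amplitude = np.empty(n_neurons)
    selectivity = np.empty(n_neurons)
    onset = np.empty(n_neurons)

    for i in range(n_neurons):
        rng = np.random.default_rng(neuron_seeds[i])
        spec = specs[labels[i]]
        amp_fn = spec.amplitude_dist or _default_amplitude
        sel_fn = spec.selectivity_dist or _default_selectivity
        preferred[i] = classes[int(rng.integers(0, 2))]
        amplitude[i] = amp_fn(rng)
        selectivity[i] = sel_fn(rng)
        gain = np.where(trial_class == preferred[i], 1.0, selectivity[i])
        clean = amplitude[i] * gain[:, None] * np.stack(
            [kernels[(labels[i], d)] for d in delays]
        )
        dff[i] = clean + noise_sd * rng.standard_normal(clean.shape)
        if make_raw:
            raw[i] = clean + noise_sd * rng.standard_normal(clean.shape)
        onset[i] = spec.onset_time(uniq_delays.max(), stim_dur, resp_dur)

    traces = TrialAlignedTraces(dff=dff, time_s=t, table=table.reset_index(drop=True),
                                raw_dff=raw, baseline_window=(-pre_dur, 0.0))
    truth = GroundTruth(archetype=labels, preferred=preferred,
                        amplitude=amplitude, selectivity=selectivity,
                        onset_latency=onset, region=region)
    return traces, truth


# ---------------------------------------------------------------------------
# imaging movies
# ---------------------------------------------------------------------------

@dataclass
class MovieConfig:
    """Geometry and noise of a synthetic imaging movie (one plane)."""

    frame_size: tuple[int, int] = (128, 128)   # (Y, X) px
    n_cells: int = 10
    cell_radius_um: float = 6.0
    pixel_size: float = 1.0                    # um / px
    baseline: float = 100.0                    # background intensity
    cell_gain: float = 50.0                    # added soma intensity at dff=0
    noise_sd: float = 0.0
    noise_model: str = "gaussian"              # or "poisson"
    drift_amplitude: int = 0                   # max |integer shift| per axis
    n_planes: int = 1
    plane_spacing: float = 25.0                # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        r_px = self.cell_radius_um / self.pixel_size
        if 2 * r_px + 2 > min(self.frame_size):
            raise ConfigError("cells do not fit inside the frame")


def _place_cells(mcfg: MovieConfig, rng: np.random.Generator) -> np.ndarray:
    """Labeled-int mask image with non-overlapping disk somata (0=background)."""
    ny, nx = mcfg.frame_size
    r = mcfg.cell_radius_um / mcfg.pixel_size
    yy, xx = np.mgrid[0:ny, 0:nx]
    labels = np.zeros((ny, nx), dtype=np.int32)
    centers: list[tuple[float, float]] = []
    margin = r + 1
    for k in range(1, mcfg.n_cells + 1):
        for _ in range(2000):
            cy = rng.uniform(margin, ny - margin)
            cx = rng.uniform(margin, nx - margin)
            if all((cy - y0) ** 2 + (cx - x0) ** 2 >= (2 * r + 2) ** 2
                   for y0, x0 in centers):
                break
        else:
            raise ConfigError("could not place cells without overlap")
        centers.append((cy, cx))
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = k
    return labels


def generate_movie(
    mcfg: MovieConfig, cell_traces: np.ndarray,
    shifts: Optional[np.ndarray] = None,
) -> tuple[Movie, GroundTruth]:
    """Render a movie of disk somata modulated by the given ΔF/F traces.

    ``cell_traces`` is n_cells x T (ΔF/F); each soma's intensity is
    ``baseline + cell_gain * (1 + dff)``.  Optional global integer-pixel
    drift (explicit per-frame ``shifts``, or a random walk clipped to
    ±drift_amplitude) is applied per frame and recorded in the returned
    ground truth, as are the soma masks.
    """
    cell_traces = np.atleast_2d(np.asarray(cell_traces, dtype=float))
    if cell_traces.shape[0] < mcfg.n_cells:
        raise ConfigError("need one trace per cell")
    rng = np.random.default_rng(np.random.SeedSequence(mcfg.seed))
    labels = _place_cells(mcfg, rng)
    T = cell_traces.shape[1]
    ny, nx = mcfg.frame_size

    base = np.full((ny, nx), mcfg.baseline, dtype=float)
    frames = np.empty((T, ny, nx))
    cell_masks = [labels == k for k in range(1, mcfg.n_cells + 1)]
    if shifts is not None:
        shifts = np.asarray(shifts, dtype=int)
        if shifts.shape != (T, 2):
            raise ConfigError("shifts must be T x 2 (dy, dx)")
    elif mcfg.drift_amplitude > 0:
        steps = rng.integers(-1, 2, size=(T, 2))
        shifts = np.clip(np.cumsum(steps, axis=0),
                         -mcfg.drift_amplitude, mcfg.drift_amplitude)
        shifts[0] = 0
    else:
        shifts = np.zeros((T, 2), dtype=int)

    for f in range(T):
        img = base.copy()
        for k, mask in enumerate(cell_masks):
            img[mask] += mcfg.cell_gain * (1.0 + cell_traces[k, f])
        img = np.roll(img, tuple(shifts[f]), axis=(0, 1))
        if mcfg.noise_sd > 0:
            if mcfg.noise_model == "poisson":
                img = rng.poisson(np.clip(img, 0, None)).astype(float)
            else:
                img = img + mcfg.noise_sd * rng.standard_normal(img.shape)
        frames[f] = np.clip(img, 0.0, None)

    movie = Movie(frames=frames, frame_rate=5.0, pixel_size=mcfg.pixel_size)
    truth = GroundTruth(masks=labels, shifts=shifts)
    return movie, truth


# ---------------------------------------------------------------------------
# behavior-camera frames
# ---------------------------------------------------------------------------

EPOCHS = ("Pre", "Delay", "Response")
CONDITIONS = ("Hit", "CR")


@dataclass
class VideoConfig:
    """Synthetic behavior-camera frame sets (300 x 200 px, width x height)."""

    n_frames: int = 10                     # per condition x epoch
    frame_size: tuple[int, int] = (200, 300)   # (rows, cols) = (height, width)
    noise_sd: float = 0.0
    movement: Optional[dict] = None
    # movement = {"condition": "Hit", "epoch": "Response",
    #             "amplitude": 30.0, "center": (100, 150), "radius": 12}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigError("need >= 2 frames per condition for templates")


def generate_video_frames(config: VideoConfig) -> tuple[dict, GroundTruth]:
    """Grayscale frames per (condition, epoch), with optional injected motion.

    Returns ``frames[(condition, epoch)]`` as n x H x W arrays plus ground
    truth flagging exactly the frames that received the movement blob.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    ny, nx = config.frame_size
    yy, xx = np.mgrid[0:ny, 0:nx]
    # static scene: smooth gradient plus a fixed "snout" disk
    scene = 60.0 + 40.0 * xx / nx + 30.0 * np.exp(
        -(((yy - ny * 0.6) ** 2 + (xx - nx * 0.4) ** 2) / (2 * 25.0 ** 2)))

    frames: dict[tuple[str, str], np.ndarray] = {}
    flags: dict[tuple[str, str], np.ndarray] = {}
    for cond in CONDITIONS:
        for epoch in EPOCHS:
            stack = np.repeat(scene[None], config.n_frames, axis=0)
            moved = np.zeros(config.n_frames, dtype=bool)
            mv = config.movement
            if mv and mv["condition"] == cond and mv["epoch"] == epoch:
                cy, cx = mv.get("center", (ny // 2, nx // 2))
                rad = mv.get("radius", 10)
                blob = ((yy - cy) ** 2 + (xx - cx) ** 2 <= rad ** 2)
                stack = stack + mv.get("amplitude", 20.0) * blob[None]
                moved[:] = True
            if config.noise_sd > 0:
                stack = stack + config.noise_sd * rng.standard_normal(stack.shape)
            frames[(cond, epoch)] = stack
            flags[(cond, epoch)] = moved
    return frames, GroundTruth(frame_flags=flags)
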
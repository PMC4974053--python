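"""Movie-to-trace front end.

Registration (integer-pixel, cross-correlation to the mean image), a
pixel-wise activity map, local-adaptive-threshold segmentation of somata,
neuropil-corrected fluorescence extraction
(F_corrected = F_raw − 0.7 · F_neuropil, annulus 0–15 µm from the ROI
border excluding other ROIs), ΔF/F with F0 = mode of the fluorescence
density distribution, and removal of duplicate ROIs sampled across planes
(r > 0.5 and XY distance < 12.5 µm → keep the brighter one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_local
from skimage.measure import label as cc_label
from skimage.registration import phase_cross_correlation

from .core import Movie

NEUROPIL_COEF = 0.7
NEUROPIL_ANNULUS_UM = (0.0, 15.0)
DUP_CORR_THRESHOLD = 0.5
DUP_DIST_UM = 12.5


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_movie(movie: Movie, max_shift: int = 10) -> tuple[Movie, np.ndarray]:
    """Correct X-Y motion by integer-pixel registration to the mean image.

    Each frame is aligned to the pixel-wise mean of all frames by 2-D
    cross-correlation; out-of-frame pixels after translation are filled with
    the frame median.  Returns the registered movie and the applied (dy, dx)
    shifts per frame.
    """
    frames = movie.frames
    if np.ptp(frames) == 0:
        warnings.warn("constant movie: registration is a no-op")
        return movie, np.zeros((frames.shape[0], 2), dtype=int)
    ref = frames.mean(axis=0)
    shifts = np.zeros((frames.shape[0], 2), dtype=int)
    out = np.empty_like(frames)
    for i, frame in enumerate(frames):
        if np.ptp(frame) == 0:
            out[i] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=1)
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        dy = int(np.clip(dy, -max_shift, max_shift))
        dx = int(np.clip(dx, -max_shift, max_shift))
        shifts[i] = (dy, dx)
        out[i] = _translate(frame, dy, dx)
    reg = Movie(frames=out, frame_rate=movie.frame_rate,
                pixel_size=movie.pixel_size, plane=movie.plane)
    return reg, shifts


def _translate(frame: np.ndarray, dy: int, dx: int) -> np.ndarray:
    out = np.full_like(frame, np.median(frame))
    ny, nx = frame.shape
    ys = slice(max(dy, 0), ny + min(dy, 0))
    xs = slice(max(dx, 0), nx + min(dx, 0))
    ys_src = slice(max(-dy, 0), ny + min(-dy, 0))
    xs_src = slice(max(-dx, 0), nx + min(-dx, 0))
    out[ys, xs] = frame[ys_src, xs_src]
    return out


# ---------------------------------------------------------------------------
# activity map and segmentation
# ---------------------------------------------------------------------------

def activity_map(movie: Movie) -> np.ndarray:
    """Pixel-wise activity score in [0, 1] highlighting responsive somata.

    Score = rectified temporal skewness × mean temporal correlation with the
    8-neighborhood, then rescaled to [0, 1].  Transient calcium signals are
    positively skewed and spatially coherent over a soma, while shot noise
    is neither; the statistic is deliberately simple and swappable.
    """
    frames = movie.frames
    T = frames.shape[0]
    sd = frames.std(axis=0)
    if np.all(sd == 0):
        return np.zeros(frames.shape[1:])
    with warnings.catch_warnings():
        # constant pixels produce a harmless precision warning; they are
        # zeroed below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(frames, axis=0)
    skew = np.clip(np.nan_to_num(skew), 0.0, None)
    # z-score each pixel's time series; flat pixels contribute zero
    mu = frames.mean(axis=0)
    z = (frames - mu) / np.where(sd > 0, sd, 1.0)
    z[:, sd == 0] = 0.0
    # neighbor correlation: mean over the 8-neighborhood of E_t[z_c z_n]
    kernel = np.ones((3, 3)); kernel[1, 1] = 0.0
    acc = np.zeros(frames.shape[1:])
    for t in range(T):
        acc += z[t] * ndimage.convolve(z[t], kernel, mode="constant")
    ncorr = np.clip(acc / (8.0 * T), 0.0, None)
    score = skew * ncorr
    if score.max() > 0:
        score = score / score.max()
    return score


@dataclass
class Roi:
    mask: np.ndarray            # boolean image
    centroid: tuple[float, float]   # (y, x) in um
    plane: int = 0
    mean_fluorescence: float = 0.0


@dataclass
class RoiSet:
    rois: list[Roi] = field(default_factory=list)
    pixel_size: float = 1.0
    shape: Optional[tuple[int, int]] = None

    def __len__(self) -> int:
        return len(self.rois)

    def label_image(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.int32)
        for k, roi in enumerate(self.rois, start=1):
            out[roi.mask] = k
        return out


def segment_rois(
    score_map: np.ndarray,
    pixel_size: float = 1.0,
    min_area_um2: float = 30.0,
    max_area_um2: float = 250.0,
    block_size: int = 31,
    offset: float = -0.02,
    abs_threshold: float = 0.05,
    plane: int = 0,
    max_split_iter: int = 8,
) -> RoiSet:
    """Somata from an activity map by local adaptive threshold + iterative split.

    Connected components above a local adaptive threshold (and above a small
    absolute floor, so a pure-noise map yields nothing) are accepted when
    their area falls inside the configured soma-area range; oversized
    components are re-thresholded at increasing levels until they split into
    acceptable pieces.
    """
    if score_map.min() < -1e-9 or score_map.max() > 1 + 1e-9:
        raise ValueError("score map must lie in [0, 1]")
    area_px = lambda um2: um2 / (pixel_size ** 2)
    min_px, max_px = area_px(min_area_um2), area_px(max_area_um2)

    thr = threshold_local(score_map, block_size=block_size, offset=offset)
    binary = (score_map > thr) & (score_map > abs_threshold)
    rois: list[Roi] = []

    def accept(mask: np.ndarray) -> None:
        area = mask.sum()
        if area < min_px:
            return
        if area <= max_px:
            cy, cx = ndimage.center_of_mass(mask)
            rois.append(Roi(mask=mask, plane=plane,
                            centroid=(cy * pixel_size, cx * pixel_size)))
            return
        # oversized: raise the threshold inside the component until it splits
        level = np.percentile(score_map[mask], 50)
        sub = mask & (score_map > level)
        for _ in range(max_split_iter):
            labeled = cc_label(sub)
            parts = [labeled == k for k in range(1, labeled.max() + 1)]
            parts = [p for p in parts if p.sum() >= min_px]
            if len(parts) >= 2 or (len(parts) == 1 and parts[0].sum() <= max_px):
                for p in parts:
                    if p.sum() <= max_px:
                        accept(p)
                return
            level = level + 0.5 * (score_map[sub].max() - level) if sub.any() else level
            sub = mask & (score_map > level)

    labeled = cc_label(binary)
    for k in range(1, labeled.max() + 1):
        accept(labeled == k)
    return RoiSet(rois=rois, pixel_size=pixel_size, shape=score_map.shape)


# ---------------------------------------------------------------------------
# trace extraction, neuropil correction, ΔF/F
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceTrace:
    f_raw_soma: np.ndarray
    f_neuropil: np.ndarray
    f_corrected_soma: Optional[np.ndarray] = None
    neuropil_coef: float = NEUROPIL_COEF


def extract_traces(
    movie: Movie, rois: RoiSet,
    annulus_um: tuple[float, float] = NEUROPIL_ANNULUS_UM,
) -> list[FluorescenceTrace]:
    """Mean soma and neuropil fluorescence per ROI.

    The neuropil region is the annulus ``annulus_um`` (default 0–15 µm,
    Euclidean distance from the ROI border) with the pixels of *all* ROIs
    excluded.  If the exclusion empties the annulus it is widened to the
    nearest non-ROI pixels with a warning.
    """
    any_roi = np.zeros(movie.frames.shape[1:], dtype=bool)
    for roi in rois.rois:
        any_roi |= roi.mask
    px = movie.pixel_size
    flat = movie.frames.reshape(movie.frames.shape[0], -1)
    out = []
    for roi in rois.rois:
        dist = ndimage.distance_transform_edt(~roi.mask) * px
        lo, hi = annulus_um
        ann = (dist > lo) & (dist <= hi) & ~any_roi
        while not ann.any():
            hi += 5.0 * px
            ann = (dist > lo) & (dist <= hi) & ~any_roi
            if hi > max(movie.frames.shape[1:]) * px:
                raise ValueError("no neuropil pixels available")
        if hi != annulus_um[1]:
            warnings.warn("annulus widened to find non-ROI neuropil pixels")
        f_raw = flat[:, roi.mask.ravel()].mean(axis=1)
        f_np = flat[:, ann.ravel()].mean(axis=1)
        roi.mean_fluorescence = float(f_raw.mean())
        out.append(FluorescenceTrace(f_raw_soma=f_raw, f_neuropil=f_np))
    return out


def neuropil_correct(
    trace: FluorescenceTrace, coef: float = NEUROPIL_COEF
) -> FluorescenceTrace:
    """F_corrected(t) = F_raw_soma(t) − coef · F_neuropil(t)  (default 0.7)."""
    if trace.f_raw_soma.shape != trace.f_neuropil.shape:
        raise ValueError("raw and neuropil traces must have equal length")
    corrected = trace.f_raw_soma - coef * trace.f_neuropil
    return FluorescenceTrace(
        f_raw_soma=trace.f_raw_soma, f_neuropil=trace.f_neuropil,
        f_corrected_soma=corrected, neuropil_coef=coef,
    )


@dataclass
class DffTrace:
    dff: np.ndarray
    f0: float
    corrected: bool = True


def mode_f0(f: np.ndarray, method: str = "histogram") -> float:
    """Mode of the fluorescence density distribution.

    ``histogram``: midpoint of the tallest Freedman–Diaconis bin (default).
    ``kde``: argmax of a Gaussian KDE evaluated on a fine grid.
    """
    f = np.asarray(f, dtype=float)
    if method == "kde":
        kde = stats.gaussian_kde(f)
        grid = np.linspace(f.min(), f.max(), 512)
        return float(grid[np.argmax(kde(grid))])
    iqr = np.subtract(*np.percentile(f, [75, 25]))
    if iqr == 0 or np.ptp(f) == 0:
        return float(np.median(f))
    width = 2 * iqr / (f.size ** (1 / 3))
    n_bins = max(1, int(np.ceil(np.ptp(f) / width)))
    counts, edges = np.histogram(f, bins=n_bins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def compute_dff(f: np.ndarray, f0_method: str = "histogram") -> DffTrace:
    """ΔF/F(t) = (F(t) − F0) / F0 with F0 the mode of the F density."""
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("fluorescence must be finite")
    f0 = mode_f0(f, method=f0_method)
    if f0 <= 0:
        raise ValueError(
            "nonpositive F0; offset the fluorescence before ΔF/F")
    return DffTrace(dff=(f - f0) / f0, f0=f0)


# ---------------------------------------------------------------------------
# duplicate removal across planes
# ---------------------------------------------------------------------------

def remove_duplicates(
    traces: Sequence[np.ndarray],
    centroids_um: Sequence[tuple[float, float]],
    planes: Optional[Sequence[int]] = None,
    corr_threshold: float = DUP_CORR_THRESHOLD,
    dist_um: float = DUP_DIST_UM,
) -> np.ndarray:
    """Indices of ROIs kept after removing redundant cross-plane samples.

    Pairs with Pearson r > ``corr_threshold`` and XY centroid distance
    < ``dist_um`` (any plane pair) are redundant; the member with the lower
    average fluorescence (more likely out of plane) is dropped, iterating
    until no pair violates.  Ties keep the lower index, which makes the
    result order-independent.
    """
    n = len(traces)
    if n == 0:
        raise ValueError("need at least one ROI")
    mat = np.asarray(traces, dtype=float)
    means = mat.mean(axis=1)
    cent = np.asarray(centroids_um, dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr)
    d2 = ((cent[:, None, :] - cent[None, :, :]) ** 2).sum(-1)
    viol = (corr > corr_threshold) & (d2 < dist_um ** 2)
    np.fill_diagonal(viol, False)

    alive = np.ones(n, dtype=bool)
    while True:
        pairs = np.argwhere(np.triu(viol) & alive[:, None] & alive[None, :])
        if len(pairs) == 0:
            break
        # drop the dimmer member of the worst pair; lower index wins ties
        i, j = max(pairs, key=lambda p: corr[p[0], p[1]])
        if means[i] < means[j] or (means[i] == means[j] and i > j):
            alive[i] = False
        else:
            alive[j] = False
    return np.flatnonzero(alive)
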
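"""Trial-locked response classification, clustering and per-neuron indices.

The significance criterion is deliberately permissive per sample but strict
in aggregate: each post-onset sample is compared to the trial's baseline
with a two-sided Wilcoxon signed-rank test at p < 0.05, and a neuron counts
as responsive only if >= 10 samples are significant in the same direction
within a delay condition, for >= 2 of the 3 delays, on hit or CR trials —
and the same criterion must hold on both the neuropil-corrected and the
uncorrected ΔF/F.  Because slow-indicator transients span many samples
while licking artifacts and chance fluctuations do not, this admits weak
but reliable responses at a per-neuron chance level below 1e-9
(see :func:`criterion_chance_level`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from .core import TrialAlignedTraces

ALPHA = 0.05
MIN_SIG_SAMPLES = 10
MIN_DELAYS = 2
MIN_TRIALS = 5
EXACT_N_MAX = 50


# ---------------------------------------------------------------------------
# vectorized Wilcoxon signed-rank
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def _signed_rank_cdf(n: int) -> np.ndarray:
    """Exact CDF of W+ (sum of positive ranks) under the null, no ties."""
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    return np.cumsum(counts) / counts.sum()


def signed_rank_test(diffs: np.ndarray, axis: int = -1
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided signed-rank p-values and directions, vectorized.

    ``diffs`` holds paired differences along ``axis``.  Assumes continuous
    data (no ties, no zeros) for the fast path; slices containing zeros or
    tied magnitudes fall back to :func:`scipy.stats.wilcoxon`.  Exact null
    distribution for n <= 50, normal approximation with continuity
    correction beyond.  Direction is the sign of the median difference.
    """
    d = np.moveaxis(np.asarray(diffs, dtype=float), axis, -1)
    n = d.shape[-1]
    if n < 1:
        raise ValueError("need at least one pair")
    absd = np.abs(d)
    order = np.argsort(absd, axis=-1, kind="stable")
    ranks = np.empty(d.shape, dtype=np.int64)
    np.put_along_axis(ranks, order, np.arange(1, n + 1), axis=-1)
    w_pos = np.where(d > 0, ranks, 0).sum(axis=-1)

    if n <= EXACT_N_MAX:
        cdf = _signed_rank_cdf(n)
        p_le = cdf[w_pos]
        p_ge = 1.0 - np.where(w_pos > 0, cdf[np.maximum(w_pos - 1, 0)], 0.0)
        p = np.minimum(2.0 * np.minimum(p_le, p_ge), 1.0)
    else:
        mu = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        z = (w_pos - mu - np.sign(w_pos - mu) * 0.5) / sd
        p = 2.0 * stats.norm.sf(np.abs(z))

    # slices violating the no-ties/no-zeros assumption: exact scipy fallback
    has_zero = (d == 0).any(axis=-1)
    has_tie = (np.diff(np.sort(absd, axis=-1), axis=-1) == 0).any(axis=-1)
    bad = has_zero | has_tie
    if bad.any():
        flat = d.reshape(-1, n)
        p_flat = p.reshape(-1)
        for idx in np.flatnonzero(bad.reshape(-1)):
            row = flat[idx]
            if np.all(row == 0):
                p_flat[idx] = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p_flat[idx] = stats.wilcoxon(row, zero_method="wilcox")[1]
        p = p_flat.reshape(p.shape)

    direction = np.sign(np.median(d, axis=-1))
    return p, direction


# ---------------------------------------------------------------------------
# significance criterion
# ---------------------------------------------------------------------------

@dataclass
class SignificanceResult:
    significant: np.ndarray            # bool per neuron
    direction: np.ndarray              # +1 enhanced / -1 suppressed / 0
    n_sig_samples: dict                # (type, delay, dir) -> per-neuron counts
    qualifying: dict                   # (type, dir) -> per-neuron delay counts
    strata: list                       # (trial_type, delay) actually tested
    alpha: float = ALPHA
    min_samples: int = MIN_SIG_SAMPLES
    min_delays: int = MIN_DELAYS

    @property
    def enhanced(self) -> np.ndarray:
        return self.significant & (self.direction > 0)

    @property
    def suppressed(self) -> np.ndarray:
        return self.significant & (self.direction < 0)


def _sig_counts(tensor, table, time_s, baseline, alpha, min_trials,
                trial_types, delays, consecutive):
    """Per (type, delay): per-neuron counts of same-direction significant samples."""
    test_mask = time_s >= 0
    counts: dict[tuple, dict[int, np.ndarray]] = {}
    strata = []
    for ttype in trial_types:
        for delay in delays:
            sel = (table["outcome"] == ttype) & (table["delay_s"] == delay)
            idx = np.flatnonzero(sel.to_numpy())
            if idx.size < min_trials:
                continue
            strata.append((ttype, delay))
            block = tensor[:, idx][:, :, :]                    # n x m x T
            base = block[:, :, baseline].mean(axis=2)          # n x m
            diffs = block[:, :, test_mask] - base[:, :, None]  # n x m x Tt
            p, direc = signed_rank_test(np.moveaxis(diffs, 1, 2), axis=-1)
            for d_sign in (1, -1):
                sig = (p < alpha) & (direc == d_sign)          # n x Tt
                if consecutive:
                    c = _longest_run(sig)
                else:
                    c = sig.sum(axis=1)
                counts.setdefault((ttype, delay), {})[d_sign] = c
    return counts, strata


def _longest_run(mask: np.ndarray) -> np.ndarray:
    out = np.zeros(mask.shape[0], dtype=int)
    run = np.zeros(mask.shape[0], dtype=int)
    for t in range(mask.shape[1]):
        run = np.where(mask[:, t], run + 1, 0)
        out = np.maximum(out, run)
    return out


def test_significance(
    tr: TrialAlignedTraces,
    alpha: float = ALPHA,
    min_samples: int = MIN_SIG_SAMPLES,
    min_delays: int = MIN_DELAYS,
    min_trials: int = MIN_TRIALS,
    trial_types: tuple[str, ...] = ("hit", "CR"),
    consecutive: bool = False,
    require_raw: bool = True,
) -> SignificanceResult:
    """Flag trial-locked responsive neurons and their direction.

    Correct trials only (hit and CR).  A neuron qualifies when, for some
    trial type and direction, at least ``min_samples`` post-onset samples
    differ from baseline at p < ``alpha`` in that direction within a delay
    condition, for at least ``min_delays`` delay conditions — on the
    corrected tensor and (``require_raw``) on the uncorrected one as well.
    """
    delays = np.unique(tr.table["delay_s"].to_numpy())
    baseline = tr.baseline_mask()
    n = tr.n_neurons

    counts_c, strata = _sig_counts(tr.dff, tr.table, tr.time_s, baseline,
                                   alpha, min_trials, trial_types, delays,
                                   consecutive)
    tensors = [counts_c]
    if require_raw and tr.raw_dff is not None and tr.raw_dff is not tr.dff:
        counts_r, _ = _sig_counts(tr.raw_dff, tr.table, tr.time_s, baseline,
                                  alpha, min_trials, trial_types, delays,
                                  consecutive)
        tensors.append(counts_r)

    tested_delays = {t: [d for (tt, d) in strata if tt == t] for t in trial_types}
    if all(len(v) < min_delays for v in tested_delays.values()):
        warnings.warn("fewer than min_delays testable strata; "
                      "no neuron can qualify")

    significant = np.zeros(n, dtype=bool)
    direction = np.zeros(n)
    qualifying: dict[tuple, np.ndarray] = {}
    strength = np.zeros(n)
    for ttype in trial_types:
        for d_sign in (1, -1):
            n_qual = None
            for counts in tensors:
                q = np.zeros(n, dtype=int)
                for delay in tested_delays[ttype]:
                    c = counts.get((ttype, delay), {}).get(d_sign)
                    if c is not None:
                        q += (c >= min_samples)
                n_qual = q if n_qual is None else np.minimum(n_qual, q)
            if n_qual is None:
                n_qual = np.zeros(n, dtype=int)
            qualifying[(ttype, d_sign)] = n_qual
            hits = n_qual >= min_delays
            # total significant-sample count on corrected data breaks
            # direction ties toward the stronger response
            tot = np.zeros(n)
            for delay in tested_delays[ttype]:
                c = counts_c.get((ttype, delay), {}).get(d_sign)
                if c is not None:
                    tot += c
            newly = hits & (tot > strength)
            direction[newly] = d_sign
            strength[newly] = tot[newly]
            significant |= hits

    return SignificanceResult(
        significant=significant, direction=direction,
        n_sig_samples=counts_c, qualifying=qualifying, strata=strata,
        alpha=alpha, min_samples=min_samples, min_delays=min_delays,
    )


def criterion_chance_level(
    n_samples: int = 60,
    alpha: float = ALPHA,
    min_samples: int = MIN_SIG_SAMPLES,
    n_delays: int = 3,
    min_delays: int = MIN_DELAYS,
    n_trial_types: int = 2,
) -> float:
    """Analytic upper bound on the criterion's per-neuron false-positive rate.

    Under sample independence, a given sample is significant in a given
    direction with probability alpha/2; a trace of ``n_samples`` qualifies
    in that direction with probability P[Binom(n_samples, alpha/2) >=
    min_samples]; a union bound over the C(n_delays, min_delays) delay
    pairs, both directions and both trial types gives the neuron-level
    bound.  The additional requirement that the raw tensor agree can only
    lower the true rate and is not credited here.
    """
    p_trace = float(stats.binom.sf(min_samples - 1, n_samples, alpha / 2.0))
    p_delays = comb(n_delays, min_delays) * p_trace ** min_delays
    return 2.0 * n_trial_types * p_delays


# ---------------------------------------------------------------------------
# normalization and clustering
# ---------------------------------------------------------------------------

def normalize_response(
    tr: TrialAlignedTraces, sig: SignificanceResult
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtract and scale each neuron's ΔF/F to unit peak magnitude.

    The per-trial baseline mean is subtracted, then each neuron is divided
    by the maximum (enhanced) or |minimum| (suppressed) of its trial-
    averaged trace over correct trials, so the peak of the average response
    has magnitude 1.  Returns (normalized tensor, normalizer per neuron);
    neurons with a zero normalizer get NaN and a warning.
    """
    base = tr.dff[:, :, tr.baseline_mask()].mean(axis=2)
    centered = tr.dff - base[:, :, None]
    correct = tr.table["outcome"].isin(["hit", "CR"]).to_numpy()
    avg = centered[:, correct].mean(axis=1)            # n x T
    norm = np.where(sig.direction < 0, -avg.min(axis=1), avg.max(axis=1))
    bad = norm <= 0
    if bad.any():
        warnings.warn(f"{bad.sum()} neuron(s) with zero normalizer dropped")
    norm = np.where(bad, np.nan, norm)
    return centered / norm[:, None, None], norm


def response_features(
    tr: TrialAlignedTraces,
    sig: SignificanceResult,
    delay: Optional[float] = None,
    all_delays: bool = False,
) -> np.ndarray:
    """Per-neuron feature vectors for clustering.

    Default: the normalized trial-averaged trace on correct trials of the
    neuron's preferred trial type at the longest delay (``delay=None``);
    ``all_delays`` concatenates the three delay conditions instead.
    """
    normalized, _ = normalize_response(tr, sig)
    delays = np.unique(tr.table["delay_s"].to_numpy())
    use = delays if all_delays else [delays.max() if delay is None else delay]
    pref = preferred_types(tr, sig)
    feats = []
    for i in range(tr.n_neurons):
        per_delay = []
        for d in use:
            sel = ((tr.table["outcome"] == pref[i])
                   & (tr.table["delay_s"] == d)).to_numpy()
            if not sel.any():    # fall back to any correct trial at this delay
                sel = (tr.table["outcome"].isin(["hit", "CR"])
                       & (tr.table["delay_s"] == d)).to_numpy()
            per_delay.append(normalized[i, sel].mean(axis=0))
        feats.append(np.concatenate(per_delay))
    return np.asarray(feats)


def preferred_types(tr: TrialAlignedTraces, sig: SignificanceResult
                    ) -> np.ndarray:
    """Preferred trial type (hit/CR) per neuron: larger sign-adjusted response.

    Ties break toward hit.
    """
    r = {t: _response_magnitude(tr, sig, t) for t in ("hit", "CR")}
    return np.where(r["CR"] > r["hit"], "CR", "hit")


def _response_magnitude(tr: TrialAlignedTraces, sig: SignificanceResult,
                        ttype: str) -> np.ndarray:
    """Integrated sign-adjusted baseline-subtracted response on one type."""
    dt = float(np.median(np.diff(tr.time_s)))
    base = tr.dff[:, :, tr.baseline_mask()].mean(axis=2)
    centered = tr.dff - base[:, :, None]
    sel = (tr.table["outcome"] == ttype).to_numpy()
    if not sel.any():
        return np.zeros(tr.n_neurons)
    out = np.zeros(tr.n_neurons)
    sub = tr.table[sel]
    cen = centered[:, sel]
    for j, (_, row) in enumerate(sub.iterrows()):
        win = (tr.time_s >= 0) & (tr.time_s < row["t_spout_out"])
        out += cen[:, j, win].sum(axis=1) * dt
    out /= sel.sum()
    return np.clip(out * np.where(sig.direction < 0, -1.0, 1.0), 0.0, None)


@dataclass
class ClusterModel:
    labels: np.ndarray             # 1..K per neuron
    k: int
    cluster_means: np.ndarray      # K x n_features
    correlation: np.ndarray        # per-neuron r to its cluster mean
    pca: Optional[PCA] = None
    linkage_matrix: Optional[np.ndarray] = None
    n_recat_iter: int = 0


def _corr_to_means(feats: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Pearson r of each feature row against each cluster mean (n x K)."""
    f = feats - feats.mean(axis=1, keepdims=True)
    m = means - means.mean(axis=1, keepdims=True)
    f_n = np.linalg.norm(f, axis=1, keepdims=True)
    m_n = np.linalg.norm(m, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (f @ m.T) / (f_n * m_n.T)
    return np.nan_to_num(r, nan=-1.0)


def cluster_responses(
    features: np.ndarray,
    k: int = 6,
    n_pcs: int = 20,
    max_recat_iter: int = 10,
) -> ClusterModel:
    """PCA + Ward clustering of response features, then correlation recategorization.

    Features are projected onto the first ``n_pcs`` principal components
    (or all available, if fewer), clustered by Ward linkage with Euclidean
    distance and cut at ``k`` clusters.  Every neuron is then re-assigned to
    the cluster whose mean trace correlates best with its own response,
    iterating assignment and mean updates until stable (at most
    ``max_recat_iter`` rounds).
    """
    features = np.asarray(features, dtype=float)
    ok = np.all(np.isfinite(features), axis=1)
    if not ok.all():
        raise ValueError("features contain non-finite rows; drop them first")
    n = features.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of neurons")
    n_comp = min(n_pcs, n, features.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(features)
    link = linkage(scores, method="ward", metric="euclidean")
    labels = fcluster(link, t=k, criterion="maxclust")

    means = np.vstack([features[labels == c].mean(axis=0)
                       for c in range(1, k + 1)])
    n_iter = 0
    for n_iter in range(1, max_recat_iter + 1):
        r = _corr_to_means(features, means)
        new = np.argmax(r, axis=1) + 1
        if np.array_equal(new, labels):
            break
        labels = new
        for c in range(1, k + 1):
            sel = labels == c
            if sel.any():
                means[c - 1] = features[sel].mean(axis=0)
    r = _corr_to_means(features, means)
    corr = r[np.arange(n), labels - 1]
    return ClusterModel(labels=labels, k=k, cluster_means=means,
                        correlation=corr, pca=pca, linkage_matrix=link,
                        n_recat_iter=n_iter)


def choose_k(
    features: np.ndarray,
    candidates: Iterable[int] = range(1, 11),
    overlap_r: float = 0.9,
    n_pcs: int = 20,
) -> int:
    """Smallest K whose (K+1)-cluster cut produces two overlapping mean traces.

    The cluster count is grown until adding one more cluster yields a pair
    of cluster means with Pearson r above ``overlap_r`` — the point where
    further splits only duplicate response types.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    n_comp = min(n_pcs, n, features.shape[1])
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(features)
    link = linkage(scores, method="ward", metric="euclidean")
    cands = sorted(candidates)
    for k in cands:
        if k + 1 > n:
            return k
        labels = fcluster(link, t=k + 1, criterion="maxclust")
        means = np.vstack([features[labels == c].mean(axis=0)
                           for c in range(1, k + 2) if (labels == c).any()])
        if len(means) < 2:
            return k
        r = _corr_to_means(means, means)
        np.fill_diagonal(r, -1.0)
        if r.max() > overlap_r:
            return k
    return cands[-1]


# ---------------------------------------------------------------------------
# selectivity, tuning, latency, delay modulation
# ---------------------------------------------------------------------------

@dataclass
class SelectivityResult:
    si: np.ndarray               # NaN where undefined
    r_pref: np.ndarray
    r_nonpref: np.ndarray
    preferred: np.ndarray        # trial type per neuron


def compute_selectivity(tr: TrialAlignedTraces, sig: SignificanceResult
                        ) -> SelectivityResult:
    """SI = (R_pref − R_non-pref) / (R_pref + R_non-pref) per neuron.

    R is the time-integrated baseline-subtracted response magnitude
    (sign-adjusted for suppressed neurons, rectified) averaged over correct
    trials of one type, taken from stimulus onset through spout retraction.
    Neurons with R_pref + R_non-pref = 0 get NaN.
    """
    r_hit = _response_magnitude(tr, sig, "hit")
    r_cr = _response_magnitude(tr, sig, "CR")
    pref_is_cr = r_cr > r_hit
    r_pref = np.where(pref_is_cr, r_cr, r_hit)
    r_non = np.where(pref_is_cr, r_hit, r_cr)
    denom = r_pref + r_non
    with np.errstate(invalid="ignore", divide="ignore"):
        si = np.where(denom > 0, (r_pref - r_non) / denom, np.nan)
    return SelectivityResult(si=si, r_pref=r_pref, r_nonpref=r_non,
                             preferred=np.where(pref_is_cr, "CR", "hit"))


def compute_osi(responses: dict[float, float]) -> tuple[float, float]:
    """Orientation selectivity: OSI = (R_pref − R_orth)/(R_pref + R_orth).

    ``responses`` maps orientation (deg) to integrated response; the
    preferred orientation is the argmax and the orthogonal one is 90° away
    (mod 180).  Returns (OSI, preferred orientation).
    """
    theta_pref = max(responses, key=responses.get)
    theta_orth = (theta_pref + 90.0) % 180.0
    if theta_orth not in responses:
        raise ValueError("no response measured at the orthogonal orientation")
    r_p, r_o = responses[theta_pref], responses[theta_orth]
    if r_p + r_o == 0:
        return float("nan"), theta_pref
    return (r_p - r_o) / (r_p + r_o), theta_pref


def estimate_latency(
    mean_trace: np.ndarray,
    time_s: np.ndarray,
    baseline_window: tuple[float, float] = (-1.0, 0.0),
    up_rate: float = 1000.0,
    min_run_s: float = 1.0,
    n_sigma: float = 1.0,
) -> Optional[float]:
    """Response onset latency from a trial-averaged ΔF/F trace.

    The trace is linearly interpolated to ``up_rate`` (1 kHz); the latency
    is the first sample of the earliest run of at least ``min_run_s`` of
    consecutive samples all above baseline-mean + n_sigma·σ or all below
    baseline-mean − n_sigma·σ, measured from stimulus onset.  ``None`` when
    no sustained excursion exists.
    """
    time_s = np.asarray(time_s, dtype=float)
    mean_trace = np.asarray(mean_trace, dtype=float)
    lo, hi = baseline_window
    bmask = (time_s >= lo) & (time_s < hi)
    if bmask.sum() < 3:
        raise ValueError("baseline window too short")
    mu, sd = mean_trace[bmask].mean(), mean_trace[bmask].std(ddof=0)
    t_up = np.arange(0.0, time_s.max(), 1.0 / up_rate)
    y = np.interp(t_up, time_s, mean_trace)
    run_len = int(round(min_run_s * up_rate))
    starts = [_first_run(y > mu + n_sigma * sd, run_len),
              _first_run(y < mu - n_sigma * sd, run_len)]
    starts = [s for s in starts if s is not None]
    if not starts:
        return None
    return float(t_up[min(starts)])


def _first_run(mask: np.ndarray, run_len: int) -> Optional[int]:
    count = 0
    for i, m in enumerate(mask):
        count = count + 1 if m else 0
        if count >= run_len:
            return i - run_len + 1
    return None


def population_modal_latency(
    latencies: Sequence[float],
    rel_height: float = 0.10,
    grid_n: int = 2048,
) -> float:
    """First mode of the latency density: the smallest-latency local maximum
    of a Silverman-bandwidth Gaussian KDE exceeding ``rel_height`` of the
    global maximum.  Latency distributions are right-skewed in higher-order
    regions, so the first mode — not the mean — describes onset.
    """
    lat = np.asarray([x for x in latencies if x is not None and np.isfinite(x)])
    if lat.size == 0:
        raise ValueError("no finite latencies")
    if lat.size == 1 or np.ptp(lat) == 0:
        return float(lat[0])
    kde = stats.gaussian_kde(lat, bw_method="silverman")
    grid = np.linspace(lat.min() - 3 * kde.factor * lat.std(),
                       lat.max() + 3 * kde.factor * lat.std(), grid_n)
    dens = kde(grid)
    floor = rel_height * dens.max()
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:]) \
        & (dens[1:-1] > floor)
    peaks = np.flatnonzero(interior) + 1
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    return float(grid[peaks[0]])


@dataclass
class DelayModulationResult:
    slopes: np.ndarray
    integrals: np.ndarray          # n_neurons x n_delays
    delays: np.ndarray
    n_pos: int
    n_neg: int
    dmi: float


def delay_modulation(
    tr: TrialAlignedTraces,
    sign: str = "enhanced",
    neurons: Optional[np.ndarray] = None,
    zero_tol: float = 1e-12,
) -> DelayModulationResult:
    """Slope of integrated ΔF/F vs delay duration and the population DMI.

    Per neuron, the trial-averaged ΔF/F (correct trials) is integrated from
    stimulus onset to spout extension for each delay and a first-order
    polynomial is fit across delays.  DMI = (n_pos − n_neg)/(n_pos + n_neg)
    for enhanced populations and (n_neg − n_pos)/(n_pos + n_neg) for
    suppressed; zero-slope neurons enter neither count.
    """
    delays = np.unique(tr.table["delay_s"].to_numpy())
    if delays.size < 2:
        raise ValueError("need responses at >= 2 delay durations")
    dt = float(np.median(np.diff(tr.time_s)))
    base = tr.dff[:, :, tr.baseline_mask()].mean(axis=2)
    centered = tr.dff - base[:, :, None]
    sel_neurons = np.arange(tr.n_neurons) if neurons is None else np.asarray(neurons)

    integrals = np.zeros((sel_neurons.size, delays.size))
    for j, d in enumerate(delays):
        sel = (tr.table["outcome"].isin(["hit", "CR"])
               & (tr.table["delay_s"] == d)).to_numpy()
        spout_in = float(tr.table.loc[sel, "t_spout_in"].iloc[0])
        win = (tr.time_s >= 0) & (tr.time_s < spout_in)
        integrals[:, j] = centered[sel_neurons][:, sel][:, :, win] \
            .mean(axis=1).sum(axis=1) * dt
    slopes = np.polyfit(delays, integrals.T, 1)[0]
    n_pos = int(np.sum(slopes > zero_tol))
    n_neg = int(np.sum(slopes < -zero_tol))
    if n_pos + n_neg == 0:
        dmi = float("nan")
    else:
        dmi = (n_pos - n_neg) / (n_pos + n_neg)
        if sign == "suppressed":
            dmi = -dmi
    return DelayModulationResult(slopes=slopes, integrals=integrals,
                                 delays=delays, n_pos=n_pos, n_neg=n_neg,
                                 dmi=float(dmi))


def summary_table(tr: TrialAlignedTraces, sig: SignificanceResult,
                  model: Optional[ClusterModel] = None,
                  selectivity: Optional[SelectivityResult] = None
                  ) -> pd.DataFrame:
    """Per-neuron CSV-ready summary of classification results."""
    out = pd.DataFrame({
        "neuron": np.arange(tr.n_neurons),
        "significant": sig.significant,
        "direction": np.where(sig.direction > 0, "enhanced",
                              np.where(sig.direction < 0, "suppressed", "")),
    })
    if model is not None:
        out["cluster"] = model.labels
        out["cluster_corr"] = model.correlation
    if selectivity is not None:
        out["SI"] = selectivity.si
        out["preferred"] = selectivity.preferred
    return out
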
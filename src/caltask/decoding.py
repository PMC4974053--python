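"""Ideal-observer decoding and targeted dimensionality reduction.

Stimulus identity is decoded by comparing error trials to correct trials
with a *different* stimulus but the *same* response (miss vs CR, FA vs
hit), so that any separation reflects the stimulus and not the movement;
choice is decoded from same-stimulus different-response pairs (hit vs
miss, FA vs CR).  For each time point, every correct trial is scored by
its Euclidean distance to a leave-one-out template of the correct class
and every error trial by its distance to the all-trials template; the
auROC over the two distance samples is the ideal observer's
discrimination performance.  Significance is assessed against label-
shuffled permutations, requiring at least 3 consecutive supra-CI time
points.

Targeted dimensionality reduction regresses each neuron's response on
coded stimulus (+1 target / −1 non-target) and choice (+1 lick / −1
no-lick), projects the coefficient vectors into a de-noised PC subspace
and orthogonalizes them into unit stimulus and choice axes onto which
condition-averaged trajectories are projected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MIN_ERROR_TRIALS = 3
POP_SIZES = (1, 5, 10, 50, 100)

# (error class, correct class) pairs per contrast
CONTRAST_PAIRS = {
    "stimulus": [("miss", "CR"), ("FA", "hit")],
    "choice": [("miss", "hit"), ("FA", "CR")],
}


def _check_pop(X: np.ndarray, labels: np.ndarray) -> None:
    if X.ndim != 3:
        raise ValueError("population tensor must be trials x neurons x time")
    if len(labels) != X.shape[0]:
        raise ValueError("labels must match the trial axis")


def _available_pairs(labels: np.ndarray, contrast: str,
                     min_error: int) -> list[tuple[str, str]]:
    pairs = []
    for err, corr in CONTRAST_PAIRS[contrast]:
        if (np.sum(labels == err) >= min_error
                and np.sum(labels == corr) >= 2):
            pairs.append((err, corr))
    return pairs


def distance_auroc(d_err: np.ndarray, d_corr: np.ndarray) -> np.ndarray:
    """auROC that error-class distances exceed correct-class distances.

    Accepts 1-D samples or (trials x time) arrays; ties count 1/2, which
    makes the result identical to Mann-Whitney U / (n1 n2).
    """
    d_err = np.atleast_2d(np.asarray(d_err, dtype=float).T).T
    d_corr = np.atleast_2d(np.asarray(d_corr, dtype=float).T).T
    gt = (d_err[:, None] > d_corr[None]).sum(axis=(0, 1))
    eq = (d_err[:, None] == d_corr[None]).sum(axis=(0, 1))
    out = (gt + 0.5 * eq) / (d_err.shape[0] * d_corr.shape[0])
    return out if out.size > 1 else float(out[0])


def _pair_auroc(X: np.ndarray, err_idx: np.ndarray, corr_idx: np.ndarray
                ) -> np.ndarray:
    """auROC(t) comparing error trials to correct trials of the contrast.

    Correct trials are scored by distance to their leave-one-out class
    template, error trials by distance to the all-trials template.
    """
    C = X[corr_idx]                      # m x n x T
    E = X[err_idx]                       # k x n x T
    m = C.shape[0]
    S = C.sum(axis=0)                    # n x T
    loo = (S[None] - C) / (m - 1)        # m x n x T
    d_corr = np.linalg.norm(C - loo, axis=1)          # m x T
    d_err = np.linalg.norm(E - S[None] / m, axis=1)   # k x T
    return np.asarray(distance_auroc(d_err, d_corr))


@dataclass
class DecodingCurve:
    auroc: np.ndarray              # time series, folded to [0.5, 1] if folded
    time_s: np.ndarray
    n_neurons: int
    n_iter: int
    contrast: str
    folded: bool = True
    null_upper: Optional[np.ndarray] = None
    null_lower: Optional[np.ndarray] = None
    significant_intervals: list = field(default_factory=list)


def ideal_observer_auroc(
    X: np.ndarray,
    labels: Sequence[str],
    contrast: str,
    n_neurons: int,
    time_s: Optional[np.ndarray] = None,
    n_iter: int = 1000,
    seed: int = 0,
    min_error_trials: int = MIN_ERROR_TRIALS,
    fold: bool = True,
) -> DecodingCurve:
    """Ideal-observer auROC(t) for random populations of ``n_neurons``.

    ``X`` is trials x neurons x time; ``labels`` are hit/miss/CR/FA.  The
    auROC is averaged over ``n_iter`` random neuron subsets and over the
    available error/correct pair directions of the contrast.  With ``fold``
    the curve is reported as max(a, 1 − a), i.e. observer performance.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _check_pop(X, labels)
    if contrast not in CONTRAST_PAIRS:
        raise ValueError("contrast must be 'stimulus' or 'choice'")
    pool = X.shape[1]
    if n_neurons > pool:
        raise ValueError(f"n_neurons={n_neurons} exceeds pool of {pool}")
    pairs = _available_pairs(labels, contrast, min_error_trials)
    if not pairs:
        raise ValueError(
            f"no usable trial pair for {contrast!r}: need >= "
            f"{min_error_trials} error trials of the matching type")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    T = X.shape[2]
    acc = np.zeros(T)
    for _ in range(n_iter):
        sub = rng.choice(pool, size=n_neurons, replace=False)
        per_pair = [
            _pair_auroc(X[:, sub, :],
                        np.flatnonzero(labels == err),
                        np.flatnonzero(labels == corr))
            for err, corr in pairs
        ]
        acc += np.mean(per_pair, axis=0)
    curve = acc / n_iter
    if fold:
        curve = np.maximum(curve, 1.0 - curve)
    t = np.arange(T) if time_s is None else np.asarray(time_s)
    return DecodingCurve(auroc=curve, time_s=t, n_neurons=n_neurons,
                         n_iter=n_iter, contrast=contrast, folded=fold)


def shuffle_null(
    X: np.ndarray,
    labels: Sequence[str],
    contrast: str,
    n_neurons: int,
    n_perm: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
    min_error_trials: int = MIN_ERROR_TRIALS,
    fold: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time (lower, upper) bounds of the auROC permutation null.

    Trial labels within each error/correct pair are shuffled ``n_perm``
    times (one random neuron subset per permutation) and the central
    ``ci``% interval of the resulting auROC distribution is returned.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).copy()
    _check_pop(X, labels)
    pairs = _available_pairs(labels, contrast, min_error_trials)
    if not pairs:
        raise ValueError("no usable trial pair for the contrast")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pool = X.shape[1]
    T = X.shape[2]
    null = np.empty((n_perm, T))
    for p in range(n_perm):
        sub = rng.choice(pool, size=n_neurons, replace=False)
        per_pair = []
        for err, corr in pairs:
            idx = np.flatnonzero((labels == err) | (labels == corr))
            k = int(np.sum(labels == err))
            perm = rng.permutation(idx)
            per_pair.append(_pair_auroc(X[:, sub, :], perm[:k], perm[k:]))
        row = np.mean(per_pair, axis=0)
        null[p] = np.maximum(row, 1.0 - row) if fold else row
    lo = (100.0 - ci) / 2.0
    return (np.percentile(null, lo, axis=0),
            np.percentile(null, 100.0 - lo, axis=0))


def significance_epochs(
    curve: np.ndarray,
    upper: np.ndarray,
    time_s: Optional[np.ndarray] = None,
    min_run: int = 3,
) -> list[tuple[float, float]]:
    """Maximal runs of >= ``min_run`` consecutive supra-CI time points.

    Returns (start, stop) in seconds (stop is the time of the last
    qualifying sample).
    """
    curve = np.asarray(curve)
    upper = np.asarray(upper)
    if curve.shape != upper.shape:
        raise ValueError("curve and CI must share the time grid")
    t = np.arange(curve.size) if time_s is None else np.asarray(time_s)
    above = curve > upper
    out = []
    start = None
    for i, a in enumerate(np.append(above, False)):
        if a and start is None:
            start = i
        elif not a and start is not None:
            if i - start >= min_run:
                out.append((float(t[start]), float(t[i - 1])))
            start = None
    return out


# ---------------------------------------------------------------------------
# targeted dimensionality reduction
# ---------------------------------------------------------------------------

@dataclass
class TaskAxes:
    stimulus_axis: np.ndarray      # unit vector, n_neurons
    choice_axis: np.ndarray        # unit vector, orthogonal to stimulus_axis
    pc_basis: np.ndarray           # n_neurons x n_pcs
    order: str = "stimulus-first"


def _condition_codes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    stim = np.where(np.isin(labels, ["hit", "miss"]), 1.0, -1.0)
    choice = np.where(np.isin(labels, ["hit", "FA"]), 1.0, -1.0)
    return stim, choice


def fit_task_axes(
    X: np.ndarray,
    labels: Sequence[str],
    n_pcs: int = 10,
    order: str = "stimulus-first",
) -> TaskAxes:
    """De-mixed stimulus and choice axes from per-neuron linear regression.

    For every time point, each neuron's single-trial response is regressed
    on the coded stimulus and choice (plus intercept); the coefficient
    vector of each variable is taken at the time point where its norm
    peaks, projected into the subspace of the first ``n_pcs`` principal
    components of the condition-averaged responses (de-noising), and the
    two axes are Gram–Schmidt orthogonalized to unit length (stimulus
    first by default).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _check_pop(X, labels)
    stim, choice = _condition_codes(labels)
    if np.unique(stim).size < 2 or np.unique(choice).size < 2:
        raise ValueError("need both stimulus classes and both responses")
    # collinear codes (e.g. no error trials) make the regression singular
    if np.abs(np.corrcoef(stim, choice)[0, 1]) > 0.999:
        raise ValueError(
            "stimulus and choice codes are collinear; include error trials")
    n_trials, n_neurons, T = X.shape
    design = np.column_stack([np.ones(n_trials), stim, choice])
    betas = np.empty((T, 2, n_neurons))
    for t in range(T):
        coef, *_ = np.linalg.lstsq(design, X[:, :, t], rcond=None)
        betas[t] = coef[1:]
    b_stim = betas[np.argmax(np.linalg.norm(betas[:, 0, :], axis=1)), 0]
    b_choice = betas[np.argmax(np.linalg.norm(betas[:, 1, :], axis=1)), 1]

    # de-noising basis: PCs of condition-averaged responses
    conds = [labels == c for c in ("hit", "miss", "CR", "FA")]
    means = np.concatenate([X[c].mean(axis=0) for c in conds if c.any()],
                           axis=1)                       # neurons x (c*T)
    means = means - means.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(means, full_matrices=False)
    k = min(n_pcs, u.shape[1], n_neurons)
    basis = u[:, :k]

    proj = basis @ basis.T
    v_stim, v_choice = proj @ b_stim, proj @ b_choice
    if order == "stimulus-first":
        first, second = v_stim, v_choice
    else:
        first, second = v_choice, v_stim
    first = first / np.linalg.norm(first)
    second = second - (second @ first) * first
    second = second / np.linalg.norm(second)
    if order == "stimulus-first":
        stim_axis, choice_axis = first, second
    else:
        stim_axis, choice_axis = second, first
    return TaskAxes(stimulus_axis=stim_axis, choice_axis=choice_axis,
                    pc_basis=basis, order=order)


@dataclass
class Trajectory:
    conditions: dict               # condition -> 2 x T (choice, stimulus)
    delta_stim: np.ndarray         # hit − CR along the stimulus axis
    delta_choice: np.ndarray
    time_s: np.ndarray
    null_stim: Optional[tuple[np.ndarray, np.ndarray]] = None
    null_choice: Optional[tuple[np.ndarray, np.ndarray]] = None


def project_trajectories(
    X: np.ndarray,
    labels: Sequence[str],
    axes: TaskAxes,
    time_s: Optional[np.ndarray] = None,
    conditions: tuple[str, ...] = ("hit", "CR"),
    n_perm: int = 1000,
    seed: int = 0,
    ci: float = 95.0,
) -> Trajectory:
    """Condition-averaged state-space trajectories and hit−CR separations.

    Each condition's trial-averaged population vector is projected onto the
    (choice, stimulus) axes per time point; ΔS(t) and ΔC(t) are the hit−CR
    differences along the stimulus and choice axes, with a permutation
    confidence band from re-computing the differences after shuffling the
    hit/CR labels (axes held fixed).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    _check_pop(X, labels)
    for c in conditions:
        if not np.any(labels == c):
            raise ValueError(f"condition {c!r} absent")
    t = np.arange(X.shape[2]) if time_s is None else np.asarray(time_s)

    def proj_means(lbls):
        out = {}
        for c in conditions:
            mean = X[lbls == c].mean(axis=0)      # n x T
            out[c] = np.vstack([axes.choice_axis @ mean,
                                axes.stimulus_axis @ mean])
        return out

    conds = proj_means(labels)
    d_stim = conds["hit"][1] - conds["CR"][1]
    d_choice = conds["hit"][0] - conds["CR"][0]

    null_s = null_c = None
    if n_perm > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        idx = np.flatnonzero(np.isin(labels, ["hit", "CR"]))
        n_hit = int(np.sum(labels == "hit"))
        ns, nc = [], []
        for _ in range(n_perm):
            perm = rng.permutation(idx)
            fake = labels.copy()
            fake[perm[:n_hit]] = "hit"
            fake[perm[n_hit:]] = "CR"
            pm = proj_means(fake)
            ns.append(pm["hit"][1] - pm["CR"][1])
            nc.append(pm["hit"][0] - pm["CR"][0])
        lo = (100.0 - ci) / 2.0
        ns, nc = np.asarray(ns), np.asarray(nc)
        null_s = (np.percentile(ns, lo, axis=0),
                  np.percentile(ns, 100 - lo, axis=0))
        null_c = (np.percentile(nc, lo, axis=0),
                  np.percentile(nc, 100 - lo, axis=0))
    return Trajectory(conditions=conds, delta_stim=d_stim,
                      delta_choice=d_choice, time_s=t,
                      null_stim=null_s, null_choice=null_c)


def population_tensor(traces, sig=None, enhanced_only: bool = True,
                      delay: Optional[float] = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(trials x neurons x time, outcome labels) from trial-aligned traces.

    Restricts to enhanced significant neurons when a significance result is
    given, and to one delay condition (default: the longest) as decoding is
    run on long-delay trials where the memory period is informative.
    """
    table = traces.table
    delays = np.unique(table["delay_s"].to_numpy())
    d = delays.max() if delay is None else delay
    tsel = (table["delay_s"] == d).to_numpy()
    nsel = np.ones(traces.n_neurons, dtype=bool)
    if sig is not None:
        nsel = sig.enhanced if enhanced_only else sig.significant
    X = np.transpose(traces.dff[nsel][:, tsel], (1, 0, 2))
    return X, table.loc[tsel, "outcome"].to_numpy()
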
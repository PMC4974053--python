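"""Behavior-camera movement analysis via template difference maps.

Movement or postural change specific to go trials is measured per task
epoch (Pre-stimulus, Delay, Response) by comparing single frames to a CR
template: D_CR(x,y) = mean_f |CR_f − mean(CR_{F≠f})| is the within-
condition baseline, D_Hit(x,y) = mean_f |Hit_f − mean(CR_{F≠f})| the
cross-condition difference, and D_Sub = |D_Hit − D_CR| isolates the
Hit-specific component.  Because every frame is compared to a template
rather than the previous frame, stable postural shifts register as well
as transient movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

EPOCHS = ("Pre", "Delay", "Response")


@dataclass
class DifferenceMap:
    d_cr: np.ndarray
    d_hit: np.ndarray
    d_sub: np.ndarray
    epoch: str = ""

    @property
    def means(self) -> dict[str, float]:
        return {"D_CR": float(self.d_cr.mean()),
                "D_Hit": float(self.d_hit.mean()),
                "D_Sub": float(self.d_sub.mean())}


def template_difference(
    hit_frames: np.ndarray,
    cr_frames: np.ndarray,
    epoch: str = "",
    seed: int = 0,
) -> DifferenceMap:
    """D_CR, D_Hit and D_Sub maps for one epoch.

    Hit frame f is paired with the leave-one-out CR template that excludes
    CR frame f (pairing by enumeration order).  When there are more Hit
    frames than CR frames, the excluded CR frame for the surplus pairings
    is chosen at random (seeded); surplus CR frames are simply unused by
    D_Hit.
    """
    hit = np.asarray(hit_frames, dtype=float)
    cr = np.asarray(cr_frames, dtype=float)
    if cr.shape[0] < 2:
        raise ValueError("need >= 2 CR frames for leave-one-out templates")
    n_cr = cr.shape[0]
    total = cr.sum(axis=0)
    loo = (total[None] - cr) / (n_cr - 1)          # template excluding frame f

    d_cr = np.abs(cr - loo).mean(axis=0)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    diffs = []
    for f in range(hit.shape[0]):
        excl = f if f < n_cr else int(rng.integers(0, n_cr))
        diffs.append(np.abs(hit[f] - loo[excl]))
    d_hit = np.mean(diffs, axis=0)
    return DifferenceMap(d_cr=d_cr, d_hit=d_hit,
                         d_sub=np.abs(d_hit - d_cr), epoch=epoch)


def session_maps(frames: dict, seed: int = 0) -> dict[str, DifferenceMap]:
    """Difference maps for every epoch of one session's frame set.

    ``frames`` maps (condition, epoch) to an n x H x W stack, as produced
    by the synthetic video generator.
    """
    return {
        epoch: template_difference(frames[("Hit", epoch)],
                                   frames[("CR", epoch)],
                                   epoch=epoch, seed=seed)
        for epoch in EPOCHS
    }


@dataclass
class MovementStats:
    epoch_means: dict              # epoch -> per-session mean D_Sub values
    pairwise_p: dict               # (epoch_a, epoch_b) -> paired t p-value
    descriptive_only: bool = False


def epoch_movement_test(
    sessions: Sequence[dict],
) -> MovementStats:
    """Paired t-tests of mean D_Sub between epoch pairs across sessions.

    ``sessions`` is a list of epoch -> DifferenceMap dicts (one per
    session).  With fewer than 3 sessions only descriptive summaries are
    returned.
    """
    epoch_means = {e: np.array([s[e].means["D_Sub"] for s in sessions])
                   for e in EPOCHS}
    if len(sessions) < 3:
        warnings.warn("fewer than 3 sessions: descriptive output only")
        return MovementStats(epoch_means=epoch_means, pairwise_p={},
                             descriptive_only=True)
    pairwise = {}
    for i, a in enumerate(EPOCHS):
        for b in EPOCHS[i + 1:]:
            x, y = epoch_means[a], epoch_means[b]
            p = 1.0 if np.allclose(x, y) else float(stats.ttest_rel(x, y).pvalue)
            pairwise[(a, b)] = p
    return MovementStats(epoch_means=epoch_means, pairwise_p=pairwise)
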
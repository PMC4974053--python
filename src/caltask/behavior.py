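"""Behavioral performance: hit/false-alarm rates, d-prime, QC, laser effects.

Sensitivity is quantified with d' = Φ⁻¹(R_HIT) − Φ⁻¹(R_FA) rather than
percent correct, because d' separates discriminability from lick bias.
Rates of exactly 0 or 1 are clipped to 1/(2N) and 1 − 1/(2N) (the
log-linear correction) before the normal inverse so d' stays finite.
Sessions must exceed d' > 1 and R_HIT − R_FA > 30% to count as on-task;
photoinhibition sessions are compared laser-ON vs laser-OFF with paired
t-tests, Bonferroni-corrected over the family of epochs tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

QC_DPRIME = 1.0
QC_RATE_DIFF = 0.30


def _clip_rate(rate: float, n: int) -> float:
    lo, hi = 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)
    return min(max(rate, lo), hi)


def compute_d_prime(r_hit: float, r_fa: float, n_go: int, n_nogo: int) -> float:
    """d' = Φ⁻¹(R_HIT) − Φ⁻¹(R_FA), with extreme rates clipped by 1/(2N)."""
    if not (0.0 <= r_hit <= 1.0 and 0.0 <= r_fa <= 1.0):
        raise ValueError("rates must be in [0, 1]")
    if n_go < 1 or n_nogo < 1:
        raise ValueError("trial counts must be >= 1")
    return float(stats.norm.ppf(_clip_rate(r_hit, n_go))
                 - stats.norm.ppf(_clip_rate(r_fa, n_nogo)))


@dataclass
class SessionSummary:
    """Per-delay and overall rates, d' and contingency counts for a session."""

    per_delay: pd.DataFrame      # delay_s, n_go, n_nogo, n_hit, n_fa, R_HIT, R_FA, d_prime
    r_hit: float
    r_fa: float
    d_prime: float
    n_trials: int
    counts: dict = field(default_factory=dict)   # hit/miss/CR/FA totals


def summarize_session(
    table: pd.DataFrame, laser_on: Optional[bool] = None
) -> SessionSummary:
    """Contingency counts, response rates and d' per delay and overall.

    ``laser_on`` filters to one laser condition; ``None`` uses all trials.
    Delay strata with no go or no no-go trials are omitted with a warning.
    """
    t = table
    if laser_on is not None:
        t = t[t["laser_on"] == laser_on]
    if len(t) == 0:
        raise ValueError("no trials after filtering")
    rows = []
    for delay, grp in t.groupby("delay_s"):
        go = grp[grp["stimulus"] == "target"]
        nogo = grp[grp["stimulus"] == "nontarget"]
        if len(go) == 0 or len(nogo) == 0:
            warnings.warn(f"delay {delay}: missing a stimulus class; stratum omitted")
            continue
        r_hit = go["licked"].mean()
        r_fa = nogo["licked"].mean()
        rows.append({
            "delay_s": delay, "n_go": len(go), "n_nogo": len(nogo),
            "n_hit": int(go["licked"].sum()), "n_fa": int(nogo["licked"].sum()),
            "R_HIT": r_hit, "R_FA": r_fa,
            "d_prime": compute_d_prime(r_hit, r_fa, len(go), len(nogo)),
        })
    per_delay = pd.DataFrame(rows)
    go = t[t["stimulus"] == "target"]
    nogo = t[t["stimulus"] == "nontarget"]
    if len(go) == 0 or len(nogo) == 0:
        raise ValueError("session needs at least one go and one no-go trial")
    r_hit, r_fa = go["licked"].mean(), nogo["licked"].mean()
    counts = t["outcome"].value_counts().to_dict()
    return SessionSummary(
        per_delay=per_delay, r_hit=float(r_hit), r_fa=float(r_fa),
        d_prime=compute_d_prime(r_hit, r_fa, len(go), len(nogo)),
        n_trials=len(t), counts=counts,
    )


def session_qc(summary: SessionSummary) -> bool:
    """Minimum performance criterion: d' > 1 and R_HIT − R_FA > 30% (strict)."""
    return bool(summary.d_prime > QC_DPRIME
                and (summary.r_hit - summary.r_fa) > QC_RATE_DIFF)


@dataclass
class LaserComparison:
    """Paired laser-OFF vs laser-ON performance across sessions."""

    epoch: str
    d_off: np.ndarray
    d_on: np.ndarray
    delta_mean: float
    p_value: float
    n_comparisons: int
    alpha: float
    significant: bool
    rates: dict = field(default_factory=dict)   # same machinery on hit/FA rates


def _paired_rates(tables: Sequence[pd.DataFrame], epoch: str):
    """Per-session (OFF, ON) summaries for sessions with both conditions."""
    pairs = []
    for i, tab in enumerate(tables):
        on = tab[(tab["laser_on"]) & (tab["laser_epoch"] == epoch)]
        off = tab[~tab["laser_on"].astype(bool)]
        if len(on) == 0 or len(off) == 0:
            warnings.warn(f"session {i}: missing a laser condition; excluded")
            continue
        # restrict OFF trials to the delays that carry laser trials, so the
        # pairing compares like with like
        delays = set(on["delay_s"])
        off = off[off["delay_s"].isin(delays)]
        if len(off) == 0:
            warnings.warn(f"session {i}: no matched OFF trials; excluded")
            continue
        pairs.append((summarize_session(off), summarize_session(on)))
    return pairs


def compare_laser_conditions(
    tables: Sequence[pd.DataFrame],
    epoch: str,
    n_comparisons: int = 3,
    alpha: float = 0.05,
) -> LaserComparison:
    """Two-sided paired t-test of d' (and rates) between laser OFF/ON trials.

    ``n_comparisons`` is the size of the Bonferroni family (default 3: the
    stimulus, delay and response photoinhibition epochs).
    """
    pairs = _paired_rates(tables, epoch)
    if len(pairs) < 2:
        raise ValueError("need >= 2 sessions with both laser conditions")
    d_off = np.array([p[0].d_prime for p in pairs])
    d_on = np.array([p[1].d_prime for p in pairs])
    if np.allclose(d_off, d_on):
        p_value = 1.0
    else:
        p_value = float(stats.ttest_rel(d_on, d_off).pvalue)
    alpha_corr = alpha / n_comparisons
    rates = {}
    for name, attr in (("hit", "r_hit"), ("fa", "r_fa")):
        off = np.array([getattr(p[0], attr) for p in pairs])
        on = np.array([getattr(p[1], attr) for p in pairs])
        p_r = 1.0 if np.allclose(off, on) else float(stats.ttest_rel(on, off).pvalue)
        rates[name] = {"off": off, "on": on,
                       "p_value": p_r, "significant": bool(p_r < alpha_corr)}
    return LaserComparison(
        epoch=epoch, d_off=d_off, d_on=d_on,
        delta_mean=float(np.mean(d_on - d_off)), p_value=p_value,
        n_comparisons=n_comparisons, alpha=alpha,
        significant=bool(p_value < alpha_corr), rates=rates,
    )
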
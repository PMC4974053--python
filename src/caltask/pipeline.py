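"""Seeded end-to-end orchestration of the synthetic benchmark pipeline.

``run_all`` chains synthetic generation → (optional movie preprocessing) →
response classification/clustering → population decoding → behavioral and
movement statistics, writing CSV/JSON/HDF5 outputs plus a resolved copy of
the configuration and a structured per-stage log that echoes parameters
and neuron counts in/out of each filter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import behavior, decoding, io, movement, preproc, responses, synthetic

log = logging.getLogger("caltask")


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run (defaults mirror the task)."""

    seed: int = 0
    out_dir: str = "caltask_run"
    # synthetic session
    n_trials: int = 300
    n_neurons: int = 300
    noise_sd: float = 0.1
    region: str = "PPC"
    hit_rate: float = 0.9
    fa_rate: float = 0.2
    # stage toggles
    run_movies: bool = False
    run_decoding: bool = True
    run_movement: bool = True
    # analysis parameters
    alpha: float = 0.05
    min_samples: int = 10
    min_delays: int = 2
    k_clusters: int = 6
    n_pcs: int = 20
    neuropil_coef: float = 0.7
    dup_corr: float = 0.5
    dup_dist_um: float = 12.5
    decode_sizes: tuple[int, ...] = (1, 5, 10, 50)
    decode_iters: int = 200
    decode_perms: int = 200

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.alpha > 0.2:
            warnings.warn(f"alpha={self.alpha} is unusually permissive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("decode_sizes",):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage; returns the result bundle as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    results: dict = {"config": config.to_dict()}
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(6)]

    # --- synthetic session and traces -------------------------------------
    scfg = synthetic.SessionConfig(
        n_trials=config.n_trials, hit_rate=config.hit_rate,
        fa_rate=config.fa_rate, seed=seeds[0])
    table = synthetic.generate_session(scfg)
    io.write_trial_table(table, out / "trials.csv")
    traces, truth = synthetic.generate_traces(
        table, synthetic.REGION_MIXTURES[config.region],
        n_neurons=config.n_neurons, noise_sd=config.noise_sd, seed=seeds[1],
        region=config.region)
    io.write_traces(traces, out / "traces.h5", truth=truth)
    log.info("simulate: %d trials, %d neurons (%s mixture)",
             config.n_trials, config.n_neurons, config.region)

    # --- behavior ----------------------------------------------------------
    summary = behavior.summarize_session(table)
    results["behavior"] = {
        "d_prime": summary.d_prime, "R_HIT": summary.r_hit,
        "R_FA": summary.r_fa, "qc_pass": behavior.session_qc(summary),
        "per_delay": summary.per_delay.to_dict(orient="records"),
    }

    # --- optional movie round-trip ----------------------------------------
    if config.run_movies:
        mcfg = synthetic.MovieConfig(n_cells=10, noise_sd=1.0, seed=seeds[2])
        flat = traces.dff[:10].reshape(10, -1)[:, :200]
        movie, mtruth = synthetic.generate_movie(mcfg, flat)
        reg, shifts = preproc.register_movie(movie)
        amap = preproc.activity_map(reg)
        rois = preproc.segment_rois(amap, pixel_size=mcfg.pixel_size)
        io.write_mask_image(rois.label_image(), out / "roi_masks.tif")
        results["preproc"] = {"n_rois": len(rois),
                              "max_shift": int(np.abs(shifts).max())}
        log.info("preprocess: %d ROIs from %d ground-truth cells",
                 len(rois), mcfg.n_cells)

    # --- response analysis -------------------------------------------------
    sig = responses.test_significance(
        traces, alpha=config.alpha, min_samples=config.min_samples,
        min_delays=config.min_delays)
    n_sig = int(sig.significant.sum())
    log.info("responses: %d/%d significant (%d enhanced, %d suppressed)",
             n_sig, traces.n_neurons, int(sig.enhanced.sum()),
             int(sig.suppressed.sum()))
    results["responses"] = {
        "n_neurons": traces.n_neurons, "n_significant": n_sig,
        "n_enhanced": int(sig.enhanced.sum()),
        "n_suppressed": int(sig.suppressed.sum()),
        "chance_level": responses.criterion_chance_level(
            n_samples=int(np.sum(traces.time_s >= 0)), alpha=config.alpha,
            min_samples=config.min_samples, min_delays=config.min_delays),
    }
    if n_sig >= config.k_clusters:
        sub = _subset(traces, sig.significant)
        sub_sig = _subset_sig(sig)
        feats = responses.response_features(sub, sub_sig)
        model = responses.cluster_responses(feats, k=config.k_clusters,
                                            n_pcs=config.n_pcs)
        sel = responses.compute_selectivity(sub, sub_sig)
        dm = responses.delay_modulation(sub)
        table_out = responses.summary_table(sub, sub_sig, model, sel)
        table_out.to_csv(out / "neuron_summary.csv", index=False)
        results["responses"].update({
            "median_SI": float(np.nanmedian(sel.si)),
            "DMI": dm.dmi, "k": model.k,
        })

    # --- decoding ----------------------------------------------------------
    if config.run_decoding and n_sig >= max(config.decode_sizes):
        X, labels = decoding.population_tensor(traces, sig)
        curves = {}
        for contrast in ("stimulus", "choice"):
            try:
                sizes = [n for n in config.decode_sizes if n <= X.shape[1]]
                per_size = {}
                for n in sizes:
                    c = decoding.ideal_observer_auroc(
                        X, labels, contrast, n, time_s=traces.time_s,
                        n_iter=config.decode_iters, seed=seeds[3])
                    lo, hi = decoding.shuffle_null(
                        X, labels, contrast, n, n_perm=config.decode_perms,
                        seed=seeds[4])
                    c.null_lower, c.null_upper = lo, hi
                    c.significant_intervals = decoding.significance_epochs(
                        c.auroc, hi, traces.time_s)
                    per_size[n] = {
                        "auroc": c.auroc, "null_upper": hi,
                        "significant_intervals": c.significant_intervals,
                    }
                curves[contrast] = per_size
            except ValueError as e:
                log.warning("decode %s skipped: %s", contrast, e)
        results["decoding"] = curves

    # --- movement video -----------------------------------------------------
    if config.run_movement:
        maps = []
        for s in range(3):
            vcfg = synthetic.VideoConfig(
                n_frames=8, noise_sd=2.0, seed=seeds[5] + s,
                movement={"condition": "Hit", "epoch": "Response",
                          "amplitude": 30.0})
            frames, _ = synthetic.generate_video_frames(vcfg)
            maps.append(movement.session_maps(frames, seed=seeds[5] + s))
        stats = movement.epoch_movement_test(maps)
        results["movement"] = {
            "epoch_means": {k: v for k, v in stats.epoch_means.items()},
            "pairwise_p": {f"{a}-{b}": p
                           for (a, b), p in stats.pairwise_p.items()},
        }

    io.write_json(results, out / "results.json")
    return results


def _subset(traces, mask):
    from .core import TrialAlignedTraces
    return TrialAlignedTraces(
        dff=traces.dff[mask], time_s=traces.time_s, table=traces.table,
        raw_dff=None if traces.raw_dff is None else traces.raw_dff[mask],
        baseline_window=traces.baseline_window)


def _subset_sig(sig):
    mask = sig.significant
    return responses.SignificanceResult(
        significant=sig.significant[mask], direction=sig.direction[mask],
        n_sig_samples={}, qualifying={}, strata=sig.strata,
        alpha=sig.alpha, min_samples=sig.min_samples,
        min_delays=sig.min_delays)
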
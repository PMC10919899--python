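"""End-to-end pipeline: generate synthetic data, sweep feedback gains,
run the downstream experiments, and serialize a results bundle.

Every numeric output is a pure function of (config, seed); the emitted
manifest (config hash + seed) permits exact re-runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .basis import net_change
from .config import RunConfig, json_default, save_config
from .experiments import (
    cancellation_paradox,
    plasticity_vs_feedback,
    stimulation_experiment,
)
from .fitting import RegularizationSpec, sweep_feedback
from .synth import build_fit_dataset

__all__ = ["run_pipeline"]


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Generate -> fit sweep -> experiments; returns (and optionally writes)
    a JSON-serializable results bundle."""
    config.validate()
    dataset = build_fit_dataset(
        g_true=config.g_true, dt=config.dt, n_cells=config.n_cells,
        n_trials=config.n_trials, seed=config.seed,
        noiseless=config.noiseless)
    dataset.exclude_outlier = config.exclude_12_5_hz
    if config.no_prediction_variant:
        for key in ("pre", "post_increase", "post_decrease"):
            dataset.params_true[key].k_PT.sine_gain = {}
            dataset.params_true[key].k_PT.step_amplitude = 0.0

    reg = RegularizationSpec()
    sweep = sweep_feedback(
        dataset, g_values=config.g_list, reg=reg,
        directions=config.directions, maxiter=config.maxiter_nonvisual,
        visual_maxfev=config.visual_maxfev)

    results = {"manifest": {"seed": config.seed, "config": asdict(config),
                            "config_hash": config.digest()},
               "fits": [], "experiments": {}}
    for fit in sweep:
        results["fits"].append({
            "g": fit.g,
            "areas": {p: getattr(fit.params_pre, f"k_{p}").area()
                      for p in ("EH", "EP", "PH", "PR", "PE")},
            "net_dkPH": {d: net_change(fit.delta_filter("PH", d))
                         for d in config.directions},
            "net_dkEH": {d: net_change(fit.delta_filter("EH", d))
                         for d in config.directions},
            "cost_terms": fit.cost_terms,
        })

    for d in config.directions:
        outcome = plasticity_vs_feedback(sweep, d)
        results["experiments"][f"plasticity_{d}"] = {
            "g": outcome.g_values, "net_dkPH": outcome.net_dkPH,
            "net_dkEH": outcome.net_dkEH, "crossover_g": outcome.crossover_g}
        paradox = []
        for fit in sweep:
            try:
                c = cancellation_paradox(fit, dataset, d)
            except RuntimeError:
                # an under-converged fit can leave the lit loop unstable;
                # report it rather than abort the bundle
                paradox.append({"g": fit.g, "unstable": True})
                continue
            paradox.append({"g": fit.g, "amp_increase": c["amp_increase"],
                            "d_vestibular": abs(c["d_vestibular"]),
                            "d_visual": abs(c["d_visual"])})
        results["experiments"][f"cancellation_{d}"] = paradox

    stim = stimulation_experiment(sweep)
    results["experiments"]["stimulation"] = {
        "g": stim["g"],
        "tau": [None if not np.isfinite(t) else t for t in stim["tau"]]}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_config(config, out / "config.yaml")
        (out / "results.json").write_text(
            json.dumps(results, default=json_default, indent=1,
                       sort_keys=True))
    return results
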
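"""In-silico experiments on the fitted circuit models.

* plasticity_vs_feedback — net plasticity of the vestibular pathways across
  the feedback-gain sweep and the crossover gain g* where net Dk_PH changes
  sign from depression to potentiation.
* cancellation_paradox — Purkinje modulation during 0.5 Hz VOR cancellation
  before vs after learning (a prediction: cancellation data never enter the
  fit), with the per-pathway input decomposition that explains why activity
  increases even in models whose vestibular input depresses.
* blocked_plasticity — refits with one plastic site frozen or
  sign-constrained, testing that two sites of plasticity are required.
* population_simulation — per-cell head/eye sensitivities for a
  heterogeneous Purkinje population sharing the population-mean behavior.
* stimulation_experiment — eye-velocity decay after a brief (25 ms)
  Purkinje stimulation pulse, the direct probe of feedback strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import net_change
from .circuit import (
    CircuitParams,
    StimulusCondition,
    convolve_series,
    simulate_closed_loop,
    simulate_stimulation,
)
from .fitting import FitResult, fit_sine, finetune_nonvisual, refit_kPT_post
from .synth import FitDataset

__all__ = [
    "LearningOutcome",
    "PopulationSpec",
    "plasticity_vs_feedback",
    "cancellation_paradox",
    "purkinje_input_decomposition",
    "blocked_plasticity",
    "population_simulation",
    "stimulation_experiment",
    "decay_time_constant",
    "single_exponential_loop_decay",
]


@dataclass
class LearningOutcome:
    """Net plasticity and crossover summary for a sweep of feedback gains."""

    g_values: np.ndarray
    net_dkPH: np.ndarray
    net_dkEH: np.ndarray
    dP_vor: np.ndarray            # sp/s per deg/s, steady state
    dE_vor: np.ndarray            # deg/s per deg/s, steady state
    crossover_g: float | None     # g* where net Dk_PH = 0
    direction: str = "increase"


def plasticity_vs_feedback(sweep: list[FitResult],
                           direction: str = "increase") -> LearningOutcome:
    """Net filter changes per feedback gain and the interpolated crossover."""
    from .synth import measure_step_response

    g = np.array([f.g for f in sweep])
    dkPH = np.array([net_change(f.delta_filter("PH", direction))
                     for f in sweep])
    dkEH = np.array([net_change(f.delta_filter("EH", direction))
                     for f in sweep])
    dP, dE = [], []
    for f in sweep:
        pre = measure_step_response(f.params_pre, f.params_pre.dt)
        post = measure_step_response(f.params_post[direction],
                                     f.params_pre.dt)
        dP.append(post["P_ss"] - pre["P_ss"])
        dE.append(post["E_ss"] - pre["E_ss"])
    dkPH_s = dkPH
    cross = None
    sign_change = np.where(np.diff(np.sign(dkPH_s)) != 0)[0]
    if sign_change.size:
        i = sign_change[0]
        cross = float(g[i] - dkPH_s[i] * (g[i + 1] - g[i])
                      / (dkPH_s[i + 1] - dkPH_s[i]))
    return LearningOutcome(g_values=g, net_dkPH=dkPH, net_dkEH=dkEH,
                           dP_vor=np.array(dP), dE_vor=np.array(dE),
                           crossover_g=cross, direction=direction)


def analytic_crossover(fit: FitResult, outcome: LearningOutcome) -> float:
    """Steady-state prediction of g*: net Dk_PH = dP_VOR - dE_VOR * area(k_PE)
    crosses zero where area(k_PE) = dP_VOR / dE_VOR, i.e. at
    g* = area(k_EP) * dP_VOR / dE_VOR."""
    i = int(np.argmin(np.abs(outcome.g_values - (outcome.crossover_g or 0))))
    a_ep = fit.params_pre.k_EP.area()
    return float(a_ep * outcome.dP_vor[i] / outcome.dE_vor[i])


# ---------------------------------------------------------------------------
# VOR-cancellation paradox


def purkinje_input_decomposition(params: CircuitParams,
                                 cond: StimulusCondition) -> dict[str, np.ndarray]:
    """Per-pathway inputs to the Purkinje cells for one closed-loop solution.

    By linearity the terms sum exactly to the total modulation:
    vestibular (H * k_PH) + visual (R * k_PR + T * k_PT) + efference copy
    (E * k_PE) [+ stimulation].
    """
    from .circuit import _kpt_signal

    tr = simulate_closed_loop(params, cond)
    vest = convolve_series(params.k_PH, cond.H)
    eff = convolve_series(params.k_PE, tr.E)
    vis = np.zeros(cond.n)
    if cond.lights:
        vis = convolve_series(params.k_PR, tr.R) \
            + _kpt_signal(params.k_PT, cond)
    return {"total": tr.P, "vestibular": vest, "visual": vis,
            "efference": eff, "E": tr.E}


def cancellation_paradox(fit: FitResult, dataset: FitDataset,
                         direction: str = "increase",
                         freq: float = 0.5) -> dict:
    """Purkinje modulation during VOR cancellation pre vs post learning.

    Returns modulation amplitudes (sp/s per deg/s) and the per-pathway
    amplitude decomposition of the learning-related change.
    """
    cond = dataset.condition(f"x0_sine_{freq}")
    dec_pre = purkinje_input_decomposition(fit.params_pre, cond)
    dec_post = purkinje_input_decomposition(fit.params_post[direction], cond)
    dt = dataset.dt
    amp = cond.amplitude

    def sine_amp(x):
        fr = fit_sine(x, freq, dt, amplitude=amp)
        return fr.complex_gain

    out = {"P_pre": sine_amp(dec_pre["total"]),
           "P_post": sine_amp(dec_post["total"])}
    for k in ("vestibular", "visual", "efference"):
        out[f"d_{k}"] = sine_amp(dec_post[k]) - sine_amp(dec_pre[k])
    out["dP"] = out["P_post"] - out["P_pre"]
    # modulation amplitude referenced to the pre-learning response phase
    ref = out["P_pre"] / abs(out["P_pre"])
    out["amp_increase"] = float((out["dP"] / ref).real)
    out["decomposition_check"] = abs(
        out["dP"] - (out["d_vestibular"] + out["d_visual"]
                     + out["d_efference"]))
    return out


# ---------------------------------------------------------------------------
# blocked plasticity


def blocked_plasticity(dataset: FitDataset, g: float,
                       block: str, direction: str = "increase",
                       maxiter: int = 80) -> dict:
    """Refit with one plastic site disabled and report the consequences.

    block: "no_kPH_change" | "no_kEH_change" | "dPH_nonnegative" |
    "dPH_nonpositive".  Returns the blocked FitResult plus diagnostics
    (achieved behavioral gain change, achieved Purkinje steady-state change,
    and — for k_EH blocks — the cancellation response change).
    """
    from .fitting import RegularizationSpec, openloop_init
    from .synth import measure_step_response
    from .circuit import frequency_response_dark

    reg = RegularizationSpec()
    init = openloop_init(dataset, reg, g)
    kwargs = {}
    if block in ("no_kPH_change", "no_kEH_change"):
        kwargs["blocked"] = block
    elif block == "dPH_nonnegative":
        kwargs["sign_constrained_dPH"] = "nonnegative"
    elif block == "dPH_nonpositive":
        kwargs["sign_constrained_dPH"] = "nonpositive"
    elif block != "none":
        raise ValueError(f"unknown block mode: {block}")
    fit = finetune_nonvisual(init, dataset, g, reg, directions=(direction,),
                             maxiter=maxiter, **kwargs)
    fit.params_post[direction] = refit_kPT_post(fit, dataset, direction)

    pre = measure_step_response(fit.params_pre, dataset.dt)
    post = measure_step_response(fit.params_post[direction], dataset.dt)
    frac = dataset.post_targets[direction]["behavior_change_frac"]
    gain_post = float(np.abs(frequency_response_dark(
        fit.params_post[direction], 0.5)["E_over_H"][0]))
    return {
        "fit": fit,
        "gain_post": gain_post,
        "dP_ss_norm": (post["P_ss"] - pre["P_ss"]) / frac,
        "P_target_norm": (dataset.post_targets[direction]["P_ss"]
                          - dataset.post_targets["pre"]["P_ss"]) / frac,
        "cancellation": cancellation_paradox(fit, dataset, direction),
    }


# ---------------------------------------------------------------------------
# population simulation


@dataclass
class PopulationSpec:
    """Per-cell scaling of k_PH and k_PR (normal, unit mean, re-normalized
    so the population mean is exactly one — required for stability when the
    population average closes the loop)."""

    n_cells: int = 20
    sigma_kPH: float = 0.25
    sigma_kPR: float = 0.4
    normalize: bool = True

    @classmethod
    def no_feedback(cls) -> "PopulationSpec":
        return cls(sigma_kPH=0.25, sigma_kPR=0.4)

    @classmethod
    def strong_feedback(cls) -> "PopulationSpec":
        return cls(sigma_kPH=0.1, sigma_kPR=20.0)


def population_simulation(fit: FitResult, dataset: FitDataset,
                          spec: PopulationSpec, seed: int = 0,
                          direction: str = "increase") -> dict:
    """Head/eye sensitivities for a heterogeneous Purkinje population.

    Head sensitivity: modulation amplitude during 0.5 Hz VOR cancellation;
    eye sensitivity: modulation amplitude during 0.5 Hz pursuit — both per
    deg/s of stimulus, pre and post learning.  Each cell's k_PH and k_PR are
    scaled by random factors; the population mean (scale exactly 1) drives
    the shared closed-loop behavior, and each cell reads out the shared
    eye/slip signals.
    """
    rng = np.random.default_rng(seed)
    sc = np.column_stack([
        1.0 + spec.sigma_kPH * rng.standard_normal(spec.n_cells),
        1.0 + spec.sigma_kPR * rng.standard_normal(spec.n_cells)])
    if spec.normalize:
        sc -= sc.mean(axis=0) - 1.0

    cond_cancel = dataset.condition("x0_sine_0.5")
    cond_pursuit = dataset.condition("pursuit_sine_0.5")
    out = {"scales": sc}
    for label, params in (("pre", fit.params_pre),
                          ("post", fit.params_post[direction])):
        rows = []
        for cond in (cond_cancel, cond_pursuit):
            dec = purkinje_input_decomposition(params, cond)
            amps = []
            for c in range(spec.n_cells):
                p_cell = (sc[c, 0] * dec["vestibular"]
                          + sc[c, 1] * dec["visual"] + dec["efference"])
                fr = fit_sine(p_cell, cond.frequency, dataset.dt,
                              amplitude=cond.amplitude)
                amps.append(fr.gain)
            rows.append(np.array(amps))
        out[f"head_sensitivity_{label}"] = rows[0]
        out[f"eye_sensitivity_{label}"] = rows[1]
    return out


# ---------------------------------------------------------------------------
# transient stimulation


def decay_time_constant(E: np.ndarray, dt: float, t_offset: float,
                        fit_range: tuple[float, float] = (0.8, 0.1)
                        ) -> float:
    """Log-linear decay constant of |E| after stimulus offset.

    Fits log|E| over the first decade of decay (envelope between
    `fit_range` fractions of the post-offset peak).  Returns np.inf if the
    response does not decay below the lower fraction within the trace.
    """
    i0 = int(round(t_offset / dt))
    env = np.abs(E[i0:])
    if env.size == 0 or env.max() == 0:
        return 0.0
    ipk = int(np.argmax(env))
    env = env[ipk:]
    hi, lo = fit_range
    below = np.where(env < hi * env[0])[0]
    if below.size == 0:
        return np.inf
    start = below[0]
    end_candidates = np.where(env < lo * env[0])[0]
    if end_candidates.size == 0:
        return np.inf
    end = end_candidates[0]
    if end - start < 4:
        start = max(0, end - 4)
    t = np.arange(start, end) * dt
    y = np.log(env[start:end])
    slope = np.polyfit(t, y, 1)[0]
    if slope >= 0:
        return np.inf
    return float(-1.0 / slope)


def stimulation_experiment(sweep: list[FitResult],
                           pulse_duration: float = 25e-3,
                           t_total: float = 2.0) -> dict:
    """Eye-velocity responses to a brief Purkinje stimulation pulse per g.

    Responses are amplitude-normalized for comparison across feedback
    gains; decay time constants are estimated from the post-offset envelope.
    """
    out = {"g": [], "tau": [], "E_norm": [], "t": None}
    for fit in sweep:
        tr = simulate_stimulation(fit.params_pre,
                                  pulse_duration=pulse_duration,
                                  t_total=t_total)
        t_off = 50e-3 + pulse_duration
        tau = decay_time_constant(tr.E, fit.params_pre.dt, t_off)
        peak = np.max(np.abs(tr.E))
        out["g"].append(fit.g)
        out["tau"].append(tau)
        out["E_norm"].append(tr.E / peak if peak > 0 else tr.E)
        out["t"] = tr.t
    out["g"] = np.array(out["g"])
    out["tau"] = np.array(out["tau"])
    return out


def single_exponential_loop_decay(g: float, tau0: float = 3e-3,
                                  dt: float = 5e-4, t_total: float = 3.0,
                                  pulse_duration: float = 25e-3) -> float:
    """Decay constant of the reduced single-exponential loop at gain g.

    The reduced loop low-passes its summed input with time constant tau0:
    y = h * (S + g y), h(t) = (1/tau0) e^{-t/tau0}.  Its closed-loop pole
    sits at -(1 - g)/tau0, so the decay constant is tau0 / (1 - g) (tau0
    itself at g = 0).  Computed here by simulating the discrete recurrence
    and fitting the envelope — an independent check of the analytic
    prediction.
    """
    from scipy.signal import lfilter

    n = int(round(t_total / dt))
    t = np.arange(n) * dt
    kern = np.exp(-t[: int(round(30 * tau0 / dt))] / tau0)
    kern /= kern.sum() * dt
    S = np.where((t >= 50e-3) & (t < 50e-3 + pulse_duration), 1.0, 0.0)
    u = np.convolve(S, kern)[:n] * dt
    # y[n] = u[n] + g * (kern * y)[n-1]  (one-sample loop delay)
    c = np.concatenate([[0.0], g * kern[:-1] * dt])
    a = np.empty(c.size)
    a[0] = 1.0
    a[1:] = -c[1:]
    y = lfilter([1.0], a, u)
    return decay_time_constant(y, dt, 50e-3 + pulse_duration)
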
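"""Closed- and open-loop simulation of the VOR circuit.

The circuit is a network of linear temporal filters:

    E(t) = -(H * k_EH)(t) + (P * k_EP)(t)
    P(t) =  (H * k_PH)(t) + (R * k_PR)(t) + (T * k_PT)(t) + (E * k_PE)(t) + S(t)

with E eye velocity (deg/s), H head velocity (deg/s), P Purkinje-cell
firing-rate modulation (sp/s, baseline-subtracted), R retinal slip
(T - H - E with lights on, 0 in darkness), T target velocity, and S an
optional direct Purkinje stimulation drive.

The efference-copy loop P -> E -> P has steady-state gain
g = sum((k_EP * k_PE)) * dt; g in [0, 1), with g = 1 marginally stable
(the loop integrates).  Closed-loop solutions are computed exactly by
rewriting the self-consistency condition as a causal recurrence
E[n] = u[n] + sum_m c[m] E[n-m] and evaluating it with an IIR filter;
the pathway latencies guarantee c[0] = 0 so the recurrence is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .basis import (
    TemporalFilter,
    TimeAxis,
    convolve_series,
    delayed_exponential_filter,
    exponential_filter,
    zero_filter,
)

__all__ = [
    "VisualPredictionSpec",
    "CircuitParams",
    "StimulusCondition",
    "Trajectory",
    "retinal_slip",
    "loop_gain",
    "set_feedback_gain",
    "simulate_closed_loop",
    "simulate_open_loop",
    "simulate_stimulation",
    "frequency_response_dark",
    "make_sine",
    "make_step",
]

KPE_TAU = 3e-3           # efference-copy filter time constant, s
KPE_TMAX = 40e-3         # support used for the discretized exponential
DIVERGENCE_BOUND = 1e6   # deg/s; aborts unstable closed-loop runs


@dataclass
class VisualPredictionSpec:
    """Visual-prediction pathway k_PT.

    The sinusoid branch is a per-frequency complex gain (sp/s per deg/s of
    target velocity; the imaginary part leads the stimulus by 90 deg).  The
    step branch is a delayed exponential filter (tau = 25 ms, delay 60 ms)
    with a free amplitude.  Pre- and post-learning values may differ: the
    prediction mechanism re-tunes online to the behavioral demand, which is
    why it is not treated as a site of plasticity.
    """

    sine_gain: dict[float, complex] = field(default_factory=dict)
    step_amplitude: float = 0.0
    step_tau: float = 25e-3
    step_delay: float = 60e-3

    def copy(self) -> "VisualPredictionSpec":
        return VisualPredictionSpec(dict(self.sine_gain), self.step_amplitude,
                                    self.step_tau, self.step_delay)

    def sine_contribution(self, freq: float, T: np.ndarray, T_quad: np.ndarray
                          ) -> np.ndarray:
        c = self.sine_gain.get(freq, 0j)
        return c.real * T + c.imag * T_quad

    def step_filter(self, axis: TimeAxis) -> TemporalFilter:
        return delayed_exponential_filter(self.step_tau, self.step_delay,
                                          self.step_amplitude, axis, "PT")


@dataclass
class CircuitParams:
    """The six-pathway filter set plus the efference-copy loop gain g."""

    k_EH: TemporalFilter
    k_EP: TemporalFilter
    k_PH: TemporalFilter
    k_PR: TemporalFilter
    k_PE: TemporalFilter
    k_PT: VisualPredictionSpec = field(default_factory=VisualPredictionSpec)
    g: float = 0.0

    @property
    def dt(self) -> float:
        return self.k_EH.axis.dt

    def copy(self) -> "CircuitParams":
        return CircuitParams(
            k_EH=self.k_EH.copy(), k_EP=self.k_EP.copy(),
            k_PH=self.k_PH.copy(), k_PR=self.k_PR.copy(),
            k_PE=self.k_PE.copy(), k_PT=self.k_PT.copy(), g=self.g,
        )


@dataclass
class StimulusCondition:
    """One entry of the stimulus battery."""

    name: str
    waveform: str                 # "sine" | "step"
    lights: bool
    dt: float
    duration: float
    H: np.ndarray                 # head velocity, deg/s
    T: np.ndarray                 # target velocity, deg/s (ignored if dark)
    S: np.ndarray | None = None   # Purkinje stimulation drive, sp/s
    frequency: float | None = None   # Hz, sine conditions
    step_duration: float | None = None
    amplitude: float = 0.0        # peak stimulus speed, deg/s
    t_onset: float = 0.0          # step onset time, s

    @property
    def n(self) -> int:
        return self.H.size

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def T_quadrature(self) -> np.ndarray:
        """90 deg phase-advanced copy of a sinusoidal target (cos for sin)."""
        if self.waveform != "sine" or self.frequency is None:
            raise ValueError("quadrature only defined for sine conditions")
        return self.amplitude * self.target_sign() * np.cos(
            2 * np.pi * self.frequency * self.t)

    def target_sign(self) -> float:
        if not self.lights:
            return 0.0
        if self.waveform == "sine" and self.amplitude > 0:
            a = np.max(np.abs(self.T))
            if a == 0:
                return 0.0
            # recover sign convention of T relative to the canonical sin
            ref = np.sin(2 * np.pi * self.frequency * self.t)
            return float(np.sign(np.dot(self.T, ref)))
        return 1.0


@dataclass
class Trajectory:
    """Solution of the circuit equations for one condition."""

    condition: StimulusCondition
    E: np.ndarray
    P: np.ndarray
    R: np.ndarray

    @property
    def t(self) -> np.ndarray:
        return self.condition.t


def retinal_slip(T: np.ndarray | None, H: np.ndarray, E: np.ndarray,
                 lights: bool) -> np.ndarray:
    """R = T - H - E with lights on (target-in-world minus gaze), 0 in darkness."""
    if not lights:
        return np.zeros_like(H)
    if T is None:
        raise ValueError("lit condition requires a target trajectory")
    return np.asarray(T, float) - np.asarray(H, float) - np.asarray(E, float)


def default_kpe(axis_dt: float, amplitude: float) -> TemporalFilter:
    axis = TimeAxis(axis_dt, KPE_TMAX)
    return exponential_filter(KPE_TAU, amplitude, axis, "PE")


def _conv_kernels(a: TemporalFilter, b: TemporalFilter) -> np.ndarray:
    """Discrete kernel of the cascade a*b (length len(a)+len(b)-1), incl. dt."""
    return np.convolve(a.kernel, b.kernel) * a.axis.dt


def loop_gain(params: CircuitParams) -> float:
    """Steady-state efference-copy loop gain: sum(k_EP * k_PE) dt."""
    c = _conv_kernels(params.k_EP, params.k_PE)
    return float(c.sum() * params.dt)


def set_feedback_gain(params: CircuitParams, g: float) -> CircuitParams:
    """Rescale k_PE so the recomputed loop gain equals g exactly.

    Must be re-applied whenever k_EP changes during fitting.
    """
    a_ep = params.k_EP.area()
    if a_ep == 0:
        raise ValueError("k_EP has zero area; loop gain undefined")
    out = params.copy()
    if g == 0:
        out.k_PE = zero_filter(params.k_PE.axis, "PE")
    else:
        # unit-area k_PE shape, then exact discrete rescale
        base = exponential_filter(KPE_TAU, 1.0, params.k_PE.axis, "PE")
        tmp = replace(out)
        tmp.k_PE = base
        g0 = loop_gain(tmp)
        out.k_PE = base.scaled(g / g0)
    out.g = g
    return out


def _closed_loop_E(params: CircuitParams, cond: StimulusCondition,
                   stimulation: bool = False) -> np.ndarray:
    """Solve the closed-loop self-consistency for E via the exact recurrence."""
    dt = params.dt
    H = cond.H
    n = cond.n

    # exogenous drive u and feedback kernel c:  E = u + c * E
    u = -convolve_series(params.k_EH, H)
    u += convolve_series(params.k_EP, convolve_series(params.k_PH, H))
    c = _conv_kernels(params.k_EP, params.k_PE)

    if cond.lights:
        # R = T - H - E feeds back through k_PR
        kep_kpr = _conv_kernels(params.k_EP, params.k_PR)
        slip_drive = cond.T - H
        u += np.convolve(slip_drive, kep_kpr)[:n] * dt
        c = _pad_add(c, -kep_kpr)
        # visual prediction acts on the known target only
        v_t = _kpt_signal(params.k_PT, cond)
        u += convolve_series(params.k_EP, v_t)
    if stimulation and cond.S is not None:
        u += convolve_series(params.k_EP, cond.S)

    u = u[:n]
    c = c * dt  # recurrence weights: E[n] = u[n] + sum_m c[m] E[n-m]
    if abs(c[0]) > 1e-12:
        raise ValueError("feedback kernel must have zero instantaneous term")
    a = np.empty(c.size)
    a[0] = 1.0
    a[1:] = -c[1:]
    E = lfilter([1.0], a, u)
    if not np.all(np.isfinite(E)) or np.max(np.abs(E)) > DIVERGENCE_BOUND:
        raise RuntimeError(
            "closed-loop simulation diverged (unstable loop, g > 1?)")
    return E


def _pad_add(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = max(a.size, b.size)
    out = np.zeros(n)
    out[: a.size] += a
    out[: b.size] += b
    return out


def _kpt_signal(kpt: VisualPredictionSpec, cond: StimulusCondition) -> np.ndarray:
    """(T * k_PT)(t) evaluated from the known target waveform."""
    if not cond.lights:
        return np.zeros(cond.n)
    if cond.waveform == "sine":
        return kpt.sine_contribution(cond.frequency, cond.T,
                                     cond.T_quadrature())
    axis = TimeAxis(cond.dt, max(0.2, 8 * kpt.step_tau + kpt.step_delay))
    return convolve_series(kpt.step_filter(axis), cond.T)


def simulate_closed_loop(params: CircuitParams, cond: StimulusCondition,
                         stimulation: bool = False) -> Trajectory:
    """Self-consistent solution of both circuit equations for one condition."""
    E = _closed_loop_E(params, cond, stimulation=stimulation)
    R = retinal_slip(cond.T if cond.lights else None, cond.H, E, cond.lights)
    P = convolve_series(params.k_PH, cond.H)
    P += convolve_series(params.k_PE, E)
    if cond.lights:
        P += convolve_series(params.k_PR, R)
        P += _kpt_signal(params.k_PT, cond)
    if stimulation and cond.S is not None:
        P += cond.S
    return Trajectory(condition=cond, E=E, P=P, R=R)


def simulate_open_loop(params: CircuitParams, cond: StimulusCondition,
                       recorded_E: np.ndarray, recorded_P: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate each equation with recorded traces on the right-hand side.

    No feedback iteration: Eq. 1 uses the recorded P, Eq. 2 uses the recorded
    E (and slip recomputed from the recorded E).
    """
    if recorded_E is None or recorded_P is None:
        raise ValueError("open-loop evaluation requires recorded E and P")
    E_hat = -convolve_series(params.k_EH, cond.H) \
        + convolve_series(params.k_EP, recorded_P)
    R = retinal_slip(cond.T if cond.lights else None, cond.H, recorded_E,
                     cond.lights)
    P_hat = convolve_series(params.k_PH, cond.H) \
        + convolve_series(params.k_PE, recorded_E)
    if cond.lights:
        P_hat += convolve_series(params.k_PR, R)
        P_hat += _kpt_signal(params.k_PT, cond)
    return E_hat, P_hat


def simulate_stimulation(params: CircuitParams, pulse_duration: float = 25e-3,
                         amplitude: float = 1.0, t_total: float = 2.0,
                         t_onset: float = 50e-3) -> Trajectory:
    """Transient Purkinje stimulation in darkness with the head stationary.

    P(t) = (H*k_PH) + (E*k_PE) + S(t) with H = 0; S = amplitude during the
    pulse.  For g -> 1 the loop integrates and the response barely decays.
    """
    dt = params.dt
    n = int(round(t_total / dt))
    t = np.arange(n) * dt
    S = np.where((t >= t_onset) & (t < t_onset + pulse_duration),
                 amplitude, 0.0)
    cond = StimulusCondition(
        name="stimulation", waveform="step", lights=False, dt=dt,
        duration=t_total, H=np.zeros(n), T=np.zeros(n), S=S,
        t_onset=t_onset, step_duration=pulse_duration)
    return simulate_closed_loop(params, cond, stimulation=True)


def frequency_response_dark(params: CircuitParams, freqs) -> dict[str, np.ndarray]:
    """Exact steady-state complex gains for sinusoidal VOR in the dark.

    Returns E/H and P/H at each frequency via the kernel DTFTs:
        E/H = (-K_EH + K_EP K_PH) / (1 - K_EP K_PE)
        P/H = K_PH + K_PE (E/H)
    """
    f = np.atleast_1d(np.asarray(freqs, dtype=float))
    K_EH = params.k_EH.dtft(f)
    K_EP = params.k_EP.dtft(f)
    K_PH = params.k_PH.dtft(f)
    K_PE = params.k_PE.dtft(f)
    denom = 1.0 - K_EP * K_PE
    EH = (-K_EH + K_EP * K_PH) / denom
    PH = K_PH + K_PE * EH
    return {"E_over_H": EH, "P_over_H": PH}


def make_sine(freq: float, amplitude: float, dt: float, n_cycles: float = 2.0,
              min_duration: float = 0.5) -> tuple[np.ndarray, float]:
    # always a whole number of cycles so cycle means vanish exactly
    cycles = max(int(np.ceil(n_cycles)), int(np.ceil(min_duration * freq)))
    duration = cycles / freq
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    return amplitude * np.sin(2 * np.pi * freq * t), duration


def make_step(step_duration: float, amplitude: float, dt: float,
              t_onset: float = 0.1, t_tail: float = 0.25,
              edge_sd: float = 5e-3) -> tuple[np.ndarray, float, float]:
    """Velocity step with Gaussian-smoothed edges (finite acceleration)."""
    from scipy.special import erf

    duration = t_onset + step_duration + t_tail
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    rise = 0.5 * (1 + erf((t - t_onset) / (np.sqrt(2) * edge_sd)))
    fall = 0.5 * (1 + erf((t - (t_onset + step_duration)) / (np.sqrt(2) * edge_sd)))
    return amplitude * (rise - fall), duration, t_onset
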
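"""Synthetic stimulus battery and "monkey-like" datasets with known ground truth.

The generator emulates the four datasets the fitting procedure consumes:

* Dataset 1 — trial-averaged Purkinje-cell modulation and eye velocity for
  25 pre-learning conditions: {vestibular-only (dark), x2, x0} x
  {sines 0.5/2/5/10 Hz at +-10 deg/s, steps 80/150/250/500 ms at 15 deg/s}
  plus a single 0.5 Hz pursuit condition at +-31.4 deg/s.
* Dataset 2 — VOR gain/phase at 15 frequencies spanning 0.5-50 Hz, before
  and after learning in both directions (12.5 Hz carries an exclusion flag).
* Datasets 3/4 — printed normalized learning-related changes in Purkinje
  modulation, and the behavioral gain change (60%) they are paired with.

The ground-truth circuit uses weak efference-copy feedback (g = 0.2) and is
shaped so that, at steady state: VOR gain is 1.0 with near-zero Purkinje
modulation in the dark, pursuit gain is 0.9 with Purkinje modulation of
1.5 sp/s per deg/s, and the post-learning models realize the printed
normalized Purkinje changes (-0.65 increase / +1.04 decrease) together with
a 60% behavioral change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .basis import (
    BasisSet,
    TimeAxis,
    assemble_filter,
    raised_cosine_basis,
    solve_warp_offset,
)
from .circuit import (
    CircuitParams,
    StimulusCondition,
    VisualPredictionSpec,
    default_kpe,
    make_sine,
    make_step,
    set_feedback_gain,
    simulate_closed_loop,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FILTER_SPECS",
    "LearningTargets",
    "NoiseSpec",
    "SyntheticRecording",
    "FitDataset",
    "default_basis",
    "true_circuit_params",
    "generate_stimulus_battery",
    "generate_recordings",
    "generate_dataset2",
    "learning_targets",
    "desaccade",
    "preprocess_rate",
    "cycle_average",
    "fold_ipsi_contra",
    "hgvp_select",
    "build_fit_dataset",
    "measure_step_response",
    "dataset2_frequencies",
]

SINE_FREQS = (0.5, 2.0, 5.0, 10.0)       # Hz
SINE_AMPLITUDE = 10.0                     # deg/s
PURSUIT_AMPLITUDE = 31.4                  # deg/s
STEP_DURATIONS = (0.08, 0.15, 0.25, 0.5)  # s
STEP_AMPLITUDE = 15.0                     # deg/s
DATASET2_N_FREQS = 15
DATASET2_RANGE = (0.5, 50.0)
DATASET2_OUTLIER = 12.5                   # Hz, flagged as excluded

# filter structural constants: (n_basis, t_max, latency, first_peak, first_half_max)
FILTER_SPECS = {
    "EH": dict(n_basis=10, t_max=50e-3, latency=5e-3,
               first_peak=7e-3, first_half_max=6e-3),
    "PH": dict(n_basis=10, t_max=50e-3, latency=5e-3,
               first_peak=7e-3, first_half_max=6e-3),
    "EP": dict(n_basis=10, t_max=150e-3, latency=1e-3,
               first_peak=7.5e-3, first_half_max=4e-3),
    "PR": dict(n_basis=12, t_max=500e-3, latency=60e-3,
               first_peak=70e-3, first_half_max=65e-3),
}

G_TRUE = 0.2
AREA_EH_PRE = 1.0       # deg/s eye per deg/s head: unity VOR
AREA_EP = 0.6           # deg/s eye per sp/s Purkinje modulation
AREA_PR = 4.0 / 3.0     # sp/s per deg/s retinal slip
PURSUIT_TARGETS = {     # complex pursuit gain E/T the truth realizes
    0.5: 0.90 + 0.0j,
    2.0: 0.85 * np.exp(-1j * np.deg2rad(10)),
    5.0: 0.70 * np.exp(-1j * np.deg2rad(25)),
    10.0: 0.50 * np.exp(-1j * np.deg2rad(45)),
}
KPT_STEP_AMPLITUDE = 0.8
BEHAVIOR_CHANGE = 0.6   # fractional VOR-gain change simulated

# smooth shape vectors (relative basis weights, normalized to unit sum)
_SHAPES = {
    "EH": np.array([3, 2.5, 2, 1.5, 1, 0.6, 0.3, 0.15, 0.08, 0.04]),
    "PH": np.array([3, 2.5, 2, 1.5, 1, 0.6, 0.3, 0.15, 0.08, 0.04]),
    "EP": np.array([2, 2, 1.8, 1.5, 1.2, 0.9, 0.6, 0.4, 0.2, 0.1]),
    "PR": np.array([0.5, 1, 1.5, 2, 2, 1.8, 1.5, 1.2, 0.9, 0.6, 0.4, 0.2]),
}


def default_basis(pathway: str, dt: float = 5e-4) -> BasisSet:
    """The per-pathway raised-cosine basis with its warp offset solved."""
    spec = FILTER_SPECS[pathway]
    axis = TimeAxis(dt, spec["t_max"] + 20 * dt)
    psi = solve_warp_offset(spec["n_basis"], spec["t_max"], spec["latency"],
                            spec["first_peak"], spec["first_half_max"])
    return raised_cosine_basis(spec["n_basis"], spec["t_max"], spec["latency"],
                               psi, axis, first_peak=spec["first_peak"])


def _shape_weights(pathway: str, area: float) -> np.ndarray:
    s = _SHAPES[pathway].astype(float)
    return s / s.sum() * area


@dataclass(frozen=True)
class LearningTargets:
    """Printed normalized Purkinje-modulation changes (sp/s per deg/s head
    velocity per fractional VOR-gain change) and related constants."""

    sine_decrease: float = 0.72
    sine_increase: float = -0.55
    step_sustained_decrease: float = 1.36
    step_sustained_increase: float = -0.75
    step_transient_increase: float = 1.62
    step_transient_decrease: float = -1.01
    behavior_change_frac: float = BEHAVIOR_CHANGE
    dataset2_freqs: tuple = ()
    excluded_freq: float = DATASET2_OUTLIER

    @property
    def averaged_decrease(self) -> float:
        return (self.sine_decrease + self.step_sustained_decrease) / 2.0

    @property
    def averaged_increase(self) -> float:
        return (self.sine_increase + self.step_sustained_increase) / 2.0


def learning_targets() -> LearningTargets:
    return LearningTargets(dataset2_freqs=tuple(dataset2_frequencies()))


def dataset2_frequencies() -> np.ndarray:
    """15 log-spaced test frequencies 0.5-50 Hz; the nearest point is pinned
    to the 12.5 Hz outlier so the exclusion flag has a concrete target."""
    f = np.geomspace(*DATASET2_RANGE, DATASET2_N_FREQS)
    f[np.argmin(np.abs(f - DATASET2_OUTLIER))] = DATASET2_OUTLIER
    return f


def true_circuit_params(g_true: float = G_TRUE, dt: float = 5e-4
                        ) -> dict[str, CircuitParams]:
    """Ground-truth circuits: pre-learning plus post-learning for both
    directions (only k_PH and k_EH change over learning).

    Steady-state construction (per deg/s of head velocity):
      pre:  E_d = -1, P_d = 0  =>  area(k_EH) = 1, area(k_PH) = area(k_PE)
      post(increase): E_d = -1.6, P_d = -0.65 * 0.6 = -0.39
      post(decrease): E_d = -0.4, P_d = +1.04 * 0.6 = +0.624
    """
    if not 0 <= g_true < 1:
        raise ValueError("generative circuit must be stable (0 <= g < 1)")
    bases = {p: default_basis(p, dt) for p in FILTER_SPECS}
    a_pe = g_true / AREA_EP

    def build(area_eh: float, area_ph: float) -> CircuitParams:
        p = CircuitParams(
            k_EH=assemble_filter(bases["EH"], _shape_weights("EH", area_eh), "EH"),
            k_EP=assemble_filter(bases["EP"], _shape_weights("EP", AREA_EP), "EP"),
            k_PH=assemble_filter(bases["PH"], _shape_weights("PH", area_ph), "PH"),
            k_PR=assemble_filter(bases["PR"], _shape_weights("PR", AREA_PR), "PR"),
            k_PE=default_kpe(dt, a_pe),
            k_PT=VisualPredictionSpec(step_amplitude=KPT_STEP_AMPLITUDE),
            g=g_true,
        )
        p = set_feedback_gain(p, g_true)
        p.k_PT.sine_gain = _solve_kpt_gains(p)
        return p

    tgt = LearningTargets()
    pre = build(AREA_EH_PRE, a_pe)

    def post(direction: str) -> CircuitParams:
        if direction == "increase":
            e_d = -(1.0 + BEHAVIOR_CHANGE)
            p_d = tgt.averaged_increase * BEHAVIOR_CHANGE
        else:
            e_d = -(1.0 - BEHAVIOR_CHANGE)
            p_d = tgt.averaged_decrease * BEHAVIOR_CHANGE
        area_ph = p_d - e_d * a_pe
        area_eh = -e_d + p_d * AREA_EP
        return build(area_eh, area_ph)

    return {"pre": pre, "post_increase": post("increase"),
            "post_decrease": post("decrease")}


def _solve_kpt_gains(params: CircuitParams) -> dict[float, complex]:
    """Per-frequency k_PT complex gains realizing the target pursuit profile.

    From E (1 - K_EP K_PE + K_EP K_PR) = T K_EP (K_PR + c):
        c = [ (E/T) (1 - K_EP K_PE + K_EP K_PR) - K_EP K_PR ] / K_EP
    """
    gains = {}
    for f, target in PURSUIT_TARGETS.items():
        K_EP = params.k_EP.dtft(f)
        K_PE = params.k_PE.dtft(f)
        K_PR = params.k_PR.dtft(f)
        gains[f] = complex(
            (target * (1 - K_EP * K_PE + K_EP * K_PR) - K_EP * K_PR) / K_EP)
    return gains


# ---------------------------------------------------------------------------
# stimulus battery


def generate_stimulus_battery(dt: float = 5e-4, n_cycles: float = 2.0
                              ) -> list[StimulusCondition]:
    """The 25 pre-learning conditions: 3 vestibular classes x 8 waveforms
    plus the single 0.5 Hz pursuit condition."""
    conds: list[StimulusCondition] = []

    def sine_cond(name, freq, H_amp, T_amp, lights):
        wave, dur = make_sine(freq, 1.0, dt, n_cycles)
        n = wave.size
        return StimulusCondition(
            name=name, waveform="sine", lights=lights, dt=dt, duration=dur,
            H=H_amp * wave, T=(T_amp * wave if lights else np.zeros(n)),
            frequency=freq, amplitude=max(abs(H_amp), abs(T_amp)))

    def step_cond(name, dur_s, H_amp, T_amp, lights):
        wave, dur, onset = make_step(dur_s, 1.0, dt)
        n = wave.size
        return StimulusCondition(
            name=name, waveform="step", lights=lights, dt=dt, duration=dur,
            H=H_amp * wave, T=(T_amp * wave if lights else np.zeros(n)),
            step_duration=dur_s, amplitude=max(abs(H_amp), abs(T_amp)),
            t_onset=onset)

    for cls, (h, t, lights) in {
        "vord": (1.0, 0.0, False),   # VOR in the dark
        "x2": (1.0, -1.0, True),     # target opposite head
        "x0": (1.0, 1.0, True),      # target with head (VOR cancellation)
    }.items():
        for f in SINE_FREQS:
            conds.append(sine_cond(f"{cls}_sine_{f}", f,
                                   h * SINE_AMPLITUDE, t * SINE_AMPLITUDE,
                                   lights))
        for d in STEP_DURATIONS:
            conds.append(step_cond(f"{cls}_step_{int(d * 1000)}", d,
                                   h * STEP_AMPLITUDE, t * STEP_AMPLITUDE,
                                   lights))
    conds.append(sine_cond("pursuit_sine_0.5", 0.5, 0.0, PURSUIT_AMPLITUDE,
                           True))
    return conds


# ---------------------------------------------------------------------------
# preprocessing chain


def desaccade(eye: np.ndarray, threshold: float = 30.0, dt: float = 5e-4,
              guard: float = 10e-3, slow_phase: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Threshold saccade removal with guard window and linear interpolation.

    Samples where |eye - slow_phase| exceeds `threshold` deg/s (slow_phase
    defaults to a 50 ms median filter) are excised together with `guard`
    seconds on each side and bridged by linear interpolation.  Returns
    (cleaned trace, boolean mask of excised samples).
    """
    eye = np.asarray(eye, dtype=float)
    if slow_phase is None:
        from scipy.ndimage import median_filter
        slow_phase = median_filter(eye, size=max(3, int(round(0.05 / dt))),
                                   mode="nearest")
    fast = np.abs(eye - slow_phase) > threshold
    if not fast.any():
        return eye.copy(), fast
    g = max(1, int(round(guard / dt)))
    mask = np.convolve(fast.astype(float), np.ones(2 * g + 1), "same") > 0
    out = eye.copy()
    idx = np.arange(eye.size)
    good = ~mask
    if good.sum() < 2:
        return out, mask
    out[mask] = np.interp(idx[mask], idx[good], eye[good])
    return out, mask


def preprocess_rate(rate: np.ndarray, dt: float = 5e-4,
                    smooth_sd: float = 10e-3, baseline_window: float = 11.0,
                    quiet_until: float | None = None,
                    periodic: bool = False) -> np.ndarray:
    """Gaussian-smooth a raw rate and remove its baseline.

    Baseline is a moving average over `baseline_window`.  Traces shorter
    than the window fall back to subtracting the pre-stimulus mean (first
    `quiet_until` seconds), or — for periodic traces spanning whole cycles,
    where the mean is exactly the baseline — the trace mean.  A blind
    fall-back to mean subtraction is logged as a warning.
    """
    rate = np.asarray(rate, dtype=float)
    smoothed = gaussian_filter1d(rate, sigma=smooth_sd / dt, mode="nearest")
    n_win = int(round(baseline_window / dt))
    if rate.size >= n_win:
        baseline = uniform_filter1d(smoothed, size=n_win, mode="nearest")
    elif quiet_until is not None and quiet_until > 5 * dt:
        baseline = smoothed[: int(round(quiet_until / dt))].mean()
    else:
        if not periodic:
            logger.warning(
                "trace shorter than the %.0f s baseline window; falling back "
                "to mean subtraction", baseline_window)
        baseline = smoothed.mean()
    return smoothed - baseline


def cycle_average(series: np.ndarray, period: float, dt: float,
                  discard: float = 0.0) -> np.ndarray:
    """Average a periodic response across complete stimulus cycles."""
    n_per = int(round(period / dt))
    start = int(round(discard / dt))
    usable = (series.size - start) // n_per
    if usable < 1:
        raise ValueError("need at least one full cycle after the discard")
    seg = series[start: start + usable * n_per].reshape(usable, n_per)
    return seg.mean(axis=0)


def fold_ipsi_contra(resp_ipsi: np.ndarray, resp_contra: np.ndarray
                     ) -> np.ndarray:
    """Average ipsiversive response with the inverted contraversive one."""
    return 0.5 * (np.asarray(resp_ipsi) - np.asarray(resp_contra))


# ---------------------------------------------------------------------------
# recordings


@dataclass
class NoiseSpec:
    """Gaussian rate noise per sample plus eye noise and saccade injection."""

    rate_sd: float = 30.0        # sp/s per 0.5 ms bin, pre-smoothing
    eye_sd: float = 2.0          # deg/s, low-passed
    eye_smooth: float = 10e-3    # s, eye-noise lowpass
    saccade_rate: float = 0.5    # per second
    saccade_speed: float = 100.0  # deg/s peak
    saccade_dur: float = 30e-3   # s
    poisson: bool = False        # emit spike counts instead of Gaussian rate
    baseline_rate: float = 75.0  # sp/s tonic Purkinje baseline
    cell_scale_sd: float = 0.15  # per-cell k_PH/k_PR heterogeneity


@dataclass
class SyntheticRecording:
    """Trial-averaged, preprocessed synthetic recordings plus ground truth."""

    battery: list[StimulusCondition]
    eye: dict[str, np.ndarray]              # trial-averaged, desaccaded
    purkinje: dict[str, np.ndarray]         # population mean modulation
    cells: list[dict[str, np.ndarray]]      # per-cell modulation traces
    cell_scales: np.ndarray                 # (n_cells, 2) k_PH/k_PR factors
    params_true: CircuitParams
    noise: NoiseSpec
    n_trials: int
    seed: int | None


def _inject_saccades(rng: np.random.Generator, n: int, dt: float,
                     spec: NoiseSpec) -> np.ndarray:
    out = np.zeros(n)
    n_sacc = rng.poisson(spec.saccade_rate * n * dt)
    w = int(round(spec.saccade_dur / dt))
    for _ in range(n_sacc):
        i0 = rng.integers(0, max(1, n - w))
        prof = np.sin(np.linspace(0, np.pi, w)) ** 2
        out[i0: i0 + w] += rng.choice([-1, 1]) * spec.saccade_speed * prof
    return out


def generate_recordings(params_true: CircuitParams,
                        battery: list[StimulusCondition],
                        n_cells: int = 5, n_trials: int = 10,
                        noise: NoiseSpec | None = None,
                        seed: int | None = 0) -> SyntheticRecording:
    """Simulate noisy trials and run them through the preprocessing chain.

    Per-cell Purkinje filters k_PH and k_PR are scaled by factors drawn from
    N(1, cell_scale_sd), normalized so the population mean is exactly one;
    the population mean closes the loop, so individual cells see the shared
    eye-velocity and slip signals.  As n_trials grows, the averaged traces
    converge to the noiseless closed-loop solution.
    """
    if params_true.g >= 1:
        raise ValueError("generative circuit must be stable (g < 1)")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)

    scales = 1.0 + noise.cell_scale_sd * rng.standard_normal((n_cells, 2))
    scales -= scales.mean(axis=0) - 1.0   # population mean exactly 1

    eye_out: dict[str, np.ndarray] = {}
    pk_out: dict[str, np.ndarray] = {}
    cells_out: list[dict[str, np.ndarray]] = [dict() for _ in range(n_cells)]

    from .circuit import _kpt_signal, convolve_series

    for cond in battery:
        clean = simulate_closed_loop(params_true, cond)
        n = cond.n
        is_step = cond.waveform == "step"
        quiet = cond.t_onset * 0.8 if is_step else None

        vest = convolve_series(params_true.k_PH, cond.H)
        eff = convolve_series(params_true.k_PE, clean.E)
        vis = np.zeros(n)
        if cond.lights:
            vis = convolve_series(params_true.k_PR, clean.R) \
                + _kpt_signal(params_true.k_PT, cond)

        eye_acc = np.zeros(n)
        cell_acc = np.zeros((n_cells, n))
        for _ in range(n_trials):
            e_noise = gaussian_filter1d(
                noise.eye_sd * rng.standard_normal(n),
                sigma=max(1.0, noise.eye_smooth / cond.dt), mode="nearest")
            raw_eye = clean.E + e_noise + _inject_saccades(rng, n, cond.dt,
                                                           noise)
            eye_acc += desaccade(raw_eye, 30.0, cond.dt)[0]
            for c in range(n_cells):
                p_clean = scales[c, 0] * vest + scales[c, 1] * vis + eff
                raw = noise.baseline_rate + p_clean
                if noise.poisson:
                    lam = np.clip(raw, 0, None) * cond.dt
                    raw = rng.poisson(lam) / cond.dt
                else:
                    raw = raw + noise.rate_sd * rng.standard_normal(n)
                cell_acc[c] += preprocess_rate(raw, cond.dt,
                                               quiet_until=quiet,
                                               periodic=not is_step)
        eye_out[cond.name] = eye_acc / n_trials
        per_cell = cell_acc / n_trials
        for c in range(n_cells):
            cells_out[c][cond.name] = per_cell[c]
        pk_out[cond.name] = per_cell.mean(axis=0)

    return SyntheticRecording(
        battery=battery, eye=eye_out, purkinje=pk_out, cells=cells_out,
        cell_scales=scales, params_true=params_true, noise=noise,
        n_trials=n_trials, seed=seed)


def hgvp_select(cells: list[dict], min_modulation: float = 10.0,
                max_phase_deg: float = 45.0) -> list[int]:
    """Indices of cells meeting the horizontal-gaze-velocity criteria.

    Each cell dict must provide, for 0.5 Hz pursuit and cancellation,
    'pursuit_amp'/'pursuit_phase_deg' (rate vs ipsiversive eye velocity) and
    'cancel_amp'/'cancel_phase_deg' (rate vs ipsiversive head velocity), and
    'horizontal_preference' (True if horizontal pursuit modulation exceeds
    vertical; synthetic cells satisfy this by construction and must flag it).
    """
    keep = []
    for i, c in enumerate(cells):
        if c["pursuit_amp"] < min_modulation:
            continue
        if abs(c["pursuit_phase_deg"]) >= max_phase_deg:
            continue
        if c["cancel_amp"] < min_modulation:
            continue
        if abs(c["cancel_phase_deg"]) >= max_phase_deg:
            continue
        if not c.get("horizontal_preference", False):
            continue
        keep.append(i)
    return keep


# ---------------------------------------------------------------------------
# dataset 2 and the assembled fitting dataset


def generate_dataset2(params_pre: CircuitParams,
                      params_post_increase: CircuitParams,
                      params_post_decrease: CircuitParams) -> pd.DataFrame:
    """VOR gain/phase at 15 frequencies, pre and post learning.

    Phase convention: 0 deg means the eye moves exactly opposite the head.
    """
    from .circuit import frequency_response_dark

    freqs = dataset2_frequencies()
    rows = {}
    for label, p in (("pre", params_pre),
                     ("post_increase", params_post_increase),
                     ("post_decrease", params_post_decrease)):
        eh = frequency_response_dark(p, freqs)["E_over_H"]
        rows[f"gain_{label}"] = np.abs(eh)
        rows[f"phase_{label}"] = np.angle(-eh, deg=True)
    df = pd.DataFrame({"freq_hz": freqs, **rows})
    df["excluded"] = np.isclose(df["freq_hz"], DATASET2_OUTLIER)
    return df


@dataclass
class FitDataset:
    """Everything the two-stage fitting procedure consumes."""

    battery: list[StimulusCondition]
    eye: dict[str, np.ndarray]
    purkinje: dict[str, np.ndarray]
    dataset2: pd.DataFrame
    exclude_outlier: bool = True
    # post-learning low-frequency neural targets, measured from the
    # post-truth circuits exactly as from experimental traces:
    post_targets: dict = field(default_factory=dict)
    params_true: dict = field(default_factory=dict)
    dt: float = 5e-4

    def dataset2_fit_rows(self) -> pd.DataFrame:
        df = self.dataset2
        return df[~df["excluded"]] if self.exclude_outlier else df

    def condition(self, name: str) -> StimulusCondition:
        for c in self.battery:
            if c.name == name:
                return c
        raise KeyError(name)


def measure_step_response(params: CircuitParams, dt: float = 5e-4
                          ) -> dict[str, float]:
    """Steady-state (100-200 ms average) and transient (0-50 ms peak)
    responses to the 500 ms dark head-velocity step, per deg/s of head."""
    wave, dur, onset = make_step(0.5, STEP_AMPLITUDE, dt)
    cond = StimulusCondition("vord_step_500", "step", False, dt, dur,
                             H=wave, T=np.zeros_like(wave),
                             step_duration=0.5, amplitude=STEP_AMPLITUDE,
                             t_onset=onset)
    tr = simulate_closed_loop(params, cond)
    i0 = cond.t.searchsorted(onset)
    ss = slice(i0 + int(0.1 / dt), i0 + int(0.2 / dt))
    trans = slice(i0, i0 + int(0.05 / dt))
    p_trans = tr.P[trans]
    return {
        "P_ss": float(tr.P[ss].mean() / STEP_AMPLITUDE),
        "E_ss": float(tr.E[ss].mean() / STEP_AMPLITUDE),
        "P_trans": float(p_trans[np.argmax(np.abs(p_trans))] / STEP_AMPLITUDE),
    }


def build_fit_dataset(g_true: float = G_TRUE, dt: float = 5e-4,
                      n_cells: int = 5, n_trials: int = 10,
                      noise: NoiseSpec | None = None, seed: int | None = 0,
                      noiseless: bool = False) -> FitDataset:
    """Generate the complete synthetic dataset the pipeline fits."""
    truths = true_circuit_params(g_true, dt)
    battery = generate_stimulus_battery(dt)

    if noiseless:
        eye, pk = {}, {}
        for cond in battery:
            tr = simulate_closed_loop(truths["pre"], cond)
            eye[cond.name] = tr.E
            pk[cond.name] = tr.P
    else:
        rec = generate_recordings(truths["pre"], battery, n_cells=n_cells,
                                  n_trials=n_trials, noise=noise, seed=seed)
        eye, pk = rec.eye, rec.purkinje

    ds2 = generate_dataset2(truths["pre"], truths["post_increase"],
                            truths["post_decrease"])

    from .circuit import frequency_response_dark
    post_targets = {}
    pre_step = measure_step_response(truths["pre"], dt)
    pre_05 = frequency_response_dark(truths["pre"], 0.5)
    for direction in ("increase", "decrease"):
        p_post = truths[f"post_{direction}"]
        step = measure_step_response(p_post, dt)
        fr = frequency_response_dark(p_post, 0.5)
        post_targets[direction] = {
            "P_ss": step["P_ss"], "E_ss": step["E_ss"],
            "P_trans": step["P_trans"],
            "dP_gain_05": complex(fr["P_over_H"][0] - pre_05["P_over_H"][0]),
            "behavior_change_frac": BEHAVIOR_CHANGE,
        }
    post_targets["pre"] = {**pre_step,
                           "P_gain_05": complex(pre_05["P_over_H"][0]),
                           "E_gain_05": complex(pre_05["E_over_H"][0])}

    return FitDataset(battery=battery, eye=eye, purkinje=pk, dataset2=ds2,
                      post_targets=post_targets, params_true=truths, dt=dt)
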
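"""Log-warped raised-cosine temporal bases and discrete causal filters.

The circuit model represents every neural pathway as a causal linear temporal
filter k(t) sampled on a uniform time grid (default 0.5 ms).  Filters fit to
data are parameterized as weighted sums of raised-cosine basis vectors that
are log-spaced in time, so short-latency structure is represented at high
resolution while long tails stay smooth with few parameters.

Each basis vector is a raised cosine in warped time x = log(u + psi), where
u = t - latency::

    B_i(u) = (cos(clip((x - phi_i) * pi / (2 delta), -pi, pi)) + 1) / 2

with centers phi_i linearly spaced (spacing delta) so adjacent vectors cross
at half height and the set tiles [0, t_max - latency].  Every vector is
truncated to the filter's support and normalized to unit discrete area, so a
filter's area (its steady-state gain) is simply the sum of its weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "TimeAxis",
    "BasisSet",
    "TemporalFilter",
    "raised_cosine_basis",
    "solve_warp_offset",
    "assemble_filter",
    "exponential_filter",
    "delayed_exponential_filter",
    "zero_filter",
    "step_response",
    "smoothed_step",
    "net_change",
    "PATHWAY_UNITS",
]

PATHWAY_UNITS = {
    "EH": "deg/s eye per deg/s head (kernel: x 1/s)",
    "EP": "deg/s eye per sp/s (kernel: x 1/s)",
    "PH": "sp/s per deg/s head (kernel: x 1/s)",
    "PR": "sp/s per deg/s slip (kernel: x 1/s)",
    "PT": "sp/s per deg/s target (kernel: x 1/s)",
    "PE": "sp/s per deg/s eye (kernel: x 1/s)",
}


@dataclass(frozen=True)
class TimeAxis:
    """Uniform causal sampling grid t = 0, dt, ..., (n-1)*dt."""

    dt: float
    t_max: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")

    @property
    def n(self) -> int:
        return int(round(self.t_max / self.dt))

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    def index(self, time: float) -> int:
        return int(round(time / self.dt))


DEFAULT_DT = 5e-4  # 0.5 ms simulation step


@dataclass(frozen=True)
class BasisSet:
    """Area-normalized raised-cosine vectors sampled on a TimeAxis."""

    vectors: np.ndarray          # (n_basis, axis.n)
    centers: np.ndarray          # phi_i, warped log-time (radians-like units)
    warp_offset: float           # psi, seconds
    latency: float               # seconds
    axis: TimeAxis

    @property
    def n_basis(self) -> int:
        return self.vectors.shape[0]


@dataclass
class TemporalFilter:
    """Discretized causal kernel k(t) with optional basis parameterization."""

    kernel: np.ndarray
    axis: TimeAxis
    pathway: str = ""
    weights: np.ndarray | None = None
    basis: BasisSet | None = None
    latency: float = 0.0
    units: str = field(default="")

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.shape != (self.axis.n,):
            raise ValueError("kernel length must match its time axis")
        if not self.units and self.pathway in PATHWAY_UNITS:
            self.units = PATHWAY_UNITS[self.pathway]

    def area(self) -> float:
        """Discrete integral sum(k) * dt — the filter's steady-state gain."""
        return float(np.sum(self.kernel) * self.axis.dt)

    def copy(self) -> "TemporalFilter":
        return TemporalFilter(
            kernel=self.kernel.copy(), axis=self.axis, pathway=self.pathway,
            weights=None if self.weights is None else self.weights.copy(),
            basis=self.basis, latency=self.latency, units=self.units,
        )

    def scaled(self, factor: float) -> "TemporalFilter":
        out = self.copy()
        out.kernel = out.kernel * factor
        if out.weights is not None:
            out.weights = out.weights * factor
        return out

    def dtft(self, freqs) -> np.ndarray:
        """Complex filter response sum(k[m] e^{-i 2 pi f m dt}) dt at freqs (Hz)."""
        f = np.atleast_1d(np.asarray(freqs, dtype=float))
        m = np.arange(self.axis.n)
        ph = np.exp(-2j * np.pi * f[:, None] * m[None, :] * self.axis.dt)
        out = ph @ self.kernel * self.axis.dt
        return out if np.ndim(freqs) else out[0]


def _warped_cosine(x: np.ndarray, center: float, delta: float) -> np.ndarray:
    arg = np.clip((x - center) * np.pi / (2.0 * delta), -np.pi, np.pi)
    return (np.cos(arg) + 1.0) / 2.0


def raised_cosine_basis(
    n_basis: int,
    t_max: float,
    latency: float,
    warp_offset: float,
    axis: TimeAxis,
    first_peak: float | None = None,
) -> BasisSet:
    """Construct a log-spaced raised-cosine basis.

    Parameters
    ----------
    n_basis : number of vectors.
    t_max : end of the filter's support, seconds (absolute time).
    latency : absolute minimum latency, seconds; vectors are zero before it.
    warp_offset : psi > 0, seconds; controls how strongly early times are
        magnified by the log warp (small psi -> sharper early vectors).
    axis : sampling grid the vectors are evaluated on.
    first_peak : absolute time of the first vector's peak; defaults to
        latency + 2 ms.

    Centers are linearly spaced in x = log(u + psi) (u = t - latency) from the
    first peak to the point where the last vector's support ends at t_max.
    All vectors are truncated to [latency, t_max] and renormalized to unit
    discrete area.
    """
    if n_basis < 1:
        raise ValueError("n_basis must be >= 1")
    if warp_offset <= 0:
        raise ValueError("warp_offset must be positive (log warp undefined)")
    if t_max <= latency:
        raise ValueError("t_max must exceed latency")
    if first_peak is None:
        first_peak = latency + 2e-3
    if not latency < first_peak < t_max:
        raise ValueError("first_peak must lie inside (latency, t_max)")

    u_peak = first_peak - latency
    u_max = t_max - latency
    phi0 = np.log(u_peak + warp_offset)
    x_end = np.log(u_max + warp_offset)
    if n_basis == 1:
        delta = (x_end - phi0) / 2.0
        centers = np.array([phi0])
    else:
        # last support end: phi_{n-1} + 2*delta = x_end, delta spacing
        # phi_{n-1} = phi0 + (n-1) delta  =>  phi0 + (n+1) delta = x_end
        delta = (x_end - phi0) / (n_basis + 1)
        centers = phi0 + delta * np.arange(n_basis)
    if delta <= 0:
        raise ValueError("degenerate basis: first_peak too close to t_max")

    t = axis.t
    u = t - latency
    valid = (u >= 0) & (t <= t_max + 0.5 * axis.dt)
    x = np.full_like(t, -np.inf)
    x[valid] = np.log(u[valid] + warp_offset)

    vectors = np.zeros((n_basis, axis.n))
    for i, c in enumerate(centers):
        v = np.where(valid, _warped_cosine(x, c, delta), 0.0)
        area = v.sum() * axis.dt
        if area <= 0:
            raise ValueError("basis vector has empty support on the grid")
        vectors[i] = v / area
    return BasisSet(vectors=vectors, centers=centers, warp_offset=warp_offset,
                    latency=latency, axis=axis)


def solve_warp_offset(
    n_basis: int,
    t_max: float,
    latency: float,
    first_peak: float,
    first_half_max: float,
    psi_bounds: tuple[float, float] = (1e-5, 0.2),
) -> float:
    """Solve psi so the first vector's rising half-max lands at a target time.

    The first vector peaks at `first_peak` by construction for any psi; psi
    sets its width.  The rising half-max of vector 0 sits at
    u = exp(phi0 - delta) - psi; we root-find psi so that this equals
    `first_half_max` (absolute time).
    """
    u_peak = first_peak - latency
    u_half = first_half_max - latency
    u_max = t_max - latency
    if not 0 < u_half < u_peak:
        raise ValueError("half-max must lie between latency and first_peak")

    def gap(psi: float) -> float:
        phi0 = np.log(u_peak + psi)
        x_end = np.log(u_max + psi)
        delta = (x_end - phi0) / (n_basis + 1 if n_basis > 1 else 2)
        return (np.exp(phi0 - delta) - psi) - u_half

    lo, hi = psi_bounds
    glo, ghi = gap(lo), gap(hi)
    if glo * ghi > 0:
        # no exact solution in range: return the bound that comes closest
        return lo if abs(glo) < abs(ghi) else hi
    return float(brentq(gap, lo, hi, xtol=1e-12))


def assemble_filter(basis: BasisSet, weights, pathway: str = "") -> TemporalFilter:
    """Weighted sum of basis vectors: k(t) = sum_i b_i B_i(t)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (basis.n_basis,):
        raise ValueError(
            f"expected {basis.n_basis} weights, got {w.shape}")
    kernel = w @ basis.vectors
    return TemporalFilter(kernel=kernel, axis=basis.axis, pathway=pathway,
                          weights=w, basis=basis, latency=basis.latency)


def exponential_filter(tau: float, amplitude: float, axis: TimeAxis,
                       pathway: str = "") -> TemporalFilter:
    """Causal exponential kernel ~ exp(-t/tau) scaled to discrete area `amplitude`."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    shape = np.exp(-axis.t / tau)
    area = shape.sum() * axis.dt
    kernel = shape * (amplitude / area) if amplitude != 0 else np.zeros(axis.n)
    return TemporalFilter(kernel=kernel, axis=axis, pathway=pathway, latency=0.0)


def delayed_exponential_filter(tau: float, delay: float, amplitude: float,
                               axis: TimeAxis, pathway: str = "") -> TemporalFilter:
    """Exponential kernel with onset delay; discrete area equals `amplitude`."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    t = axis.t
    shape = np.where(t >= delay, np.exp(-(t - delay) / tau), 0.0)
    area = shape.sum() * axis.dt
    kernel = shape * (amplitude / area) if amplitude != 0 else np.zeros(axis.n)
    return TemporalFilter(kernel=kernel, axis=axis, pathway=pathway, latency=delay)


def zero_filter(axis: TimeAxis, pathway: str = "") -> TemporalFilter:
    return TemporalFilter(kernel=np.zeros(axis.n), axis=axis, pathway=pathway)


def convolve_series(kernel: TemporalFilter, x: np.ndarray) -> np.ndarray:
    """Causal discrete convolution (k * x)[n] = sum_m k[m] x[n-m] dt."""
    x = np.asarray(x, dtype=float)
    full = np.convolve(x, kernel.kernel)[: x.size]
    return full * kernel.axis.dt


def smoothed_step(axis_n: int, dt: float, onset: float, height: float = 1.0,
                  edge_sd: float = 10e-3) -> np.ndarray:
    """Unit step with a Gaussian-smoothed edge (error-function profile)."""
    from scipy.special import erf

    t = np.arange(axis_n) * dt
    return height * 0.5 * (1.0 + erf((t - onset) / (np.sqrt(2) * edge_sd)))


def step_response(f: TemporalFilter, step: np.ndarray) -> np.ndarray:
    """Causal convolution of a kernel with a (smoothed) step input.

    Steady-state value equals kernel area x step height.
    """
    return convolve_series(f, np.asarray(step, dtype=float))


def net_change(delta: TemporalFilter) -> float:
    """Net plasticity: discrete integral of a post-minus-pre kernel difference.

    Negative = net depression, positive = net potentiation.
    """
    return delta.area()
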
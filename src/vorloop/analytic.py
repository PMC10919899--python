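"""Closed-form analysis of a simplified one-visual-pathway circuit.

Working at a single complex frequency s (steady state s = 0 uses real
values), the circuit reduces to scalar equations

    VOR in the dark:  E_d = -H_d k_EH + P_d k_EP ;  P_d = H_d k_PH + E_d k_PE
    pursuit:          E_p =  P_p k_EP            ;  P_p = R_p k_PR + E_p k_PE
    stimulation:      E_s =  P_s k_EP            ;  P_s = E_s k_PE + S

with R_p = T_p - E_p the pursuit retinal slip.  The two brainstem filters
are fully determined by the data; the three Purkinje-input filters are
degenerate — an affine one-parameter family indexed by k_PE fits the
dark + pursuit data exactly — and the stimulation condition supplies the
extra constraint that makes the solution unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "SteadyStateData",
    "ScalarFilterPoint",
    "forward_conditions",
    "closed_form_brainstem",
    "degenerate_family",
    "stimulation_response",
    "condition_cost",
    "cost_landscape",
]


@dataclass
class ScalarFilterPoint:
    """Filter values at a single complex frequency."""

    k_EH: complex
    k_EP: complex
    k_PH: complex
    k_PR: complex
    k_PE: complex


@dataclass
class SteadyStateData:
    """Complex condition gains used by the closed forms.

    H_d: head drive (dark); E_d, P_d: eye / Purkinje gains in the dark.
    T_p: pursuit target drive; E_p, P_p: pursuit gains; R_p = T_p - E_p.
    S: stimulation drive; E_s, P_s: stimulation-condition gains.
    """

    H_d: complex
    E_d: complex
    P_d: complex
    T_p: complex
    E_p: complex
    P_p: complex
    S: complex = 0.0
    E_s: complex = 0.0
    P_s: complex = 0.0
    s: complex = 0.0

    @property
    def R_p(self) -> complex:
        return self.T_p - self.E_p


def _solve_dark(fp: ScalarFilterPoint, H: complex) -> tuple[complex, complex]:
    """Self-consistent (E, P) for a dark vestibular drive H."""
    denom = 1.0 - fp.k_EP * fp.k_PE
    if denom == 0:
        raise ZeroDivisionError("singular efference-copy loop (g = 1)")
    E = H * (-fp.k_EH + fp.k_EP * fp.k_PH) / denom
    P = H * fp.k_PH + E * fp.k_PE
    return E, P


def _solve_pursuit(fp: ScalarFilterPoint, T: complex) -> tuple[complex, complex]:
    """Self-consistent (E, P) for a pursuit target drive T (slip R = T - E)."""
    denom = 1.0 - fp.k_EP * fp.k_PE + fp.k_EP * fp.k_PR
    if denom == 0:
        raise ZeroDivisionError("singular visual loop")
    E = T * fp.k_EP * fp.k_PR / denom
    P = (T - E) * fp.k_PR + E * fp.k_PE
    return E, P


def _solve_stimulation(fp: ScalarFilterPoint, S: complex
                       ) -> tuple[complex, complex]:
    denom = 1.0 - fp.k_EP * fp.k_PE
    if denom == 0:
        raise ZeroDivisionError("singular efference-copy loop (g = 1)")
    P = S / denom
    E = P * fp.k_EP
    return E, P


def forward_conditions(fp: ScalarFilterPoint, H_d: complex = 1.0,
                       T_p: complex = 1.0, S: complex = 0.0
                       ) -> SteadyStateData:
    """Generate the condition gains a given filter point produces."""
    E_d, P_d = _solve_dark(fp, H_d)
    E_p, P_p = _solve_pursuit(fp, T_p)
    E_s, P_s = _solve_stimulation(fp, S) if S != 0 else (0.0, 0.0)
    return SteadyStateData(H_d=H_d, E_d=E_d, P_d=P_d, T_p=T_p, E_p=E_p,
                           P_p=P_p, S=S, E_s=E_s, P_s=P_s)


def closed_form_brainstem(d: SteadyStateData) -> tuple[complex, complex]:
    """Unique brainstem solution:

        k_EH = (E_p P_d - E_d P_p) / (P_p H_d) ;  k_EP = E_p / P_p

    Independent of k_PE.
    """
    if d.P_p == 0:
        raise ZeroDivisionError("P_p = 0: pursuit Purkinje gain required")
    if d.H_d == 0:
        raise ZeroDivisionError("H_d = 0: dark head drive required")
    k_EP = d.E_p / d.P_p
    k_EH = (d.E_p * d.P_d - d.E_d * d.P_p) / (d.P_p * d.H_d)
    return k_EH, k_EP


def degenerate_family(k_PE: complex, d: SteadyStateData
                      ) -> tuple[complex, complex]:
    """The affine family completing a zero-residual fit for any k_PE:

        k_PH = (P_d - E_d k_PE) / H_d ;  k_PR = (P_p - k_PE E_p) / R_p
    """
    if d.H_d == 0:
        raise ZeroDivisionError("H_d = 0")
    if d.R_p == 0:
        raise ZeroDivisionError("R_p = 0: pursuit slip gain required")
    k_PH = (d.P_d - d.E_d * k_PE) / d.H_d
    k_PR = (d.P_p - k_PE * d.E_p) / d.R_p
    return k_PH, k_PR


def stimulation_response(S: complex, k_EP: complex, k_PE: complex
                         ) -> tuple[complex, complex]:
    """Sustained-stimulation responses P_s = S / (1 - k_EP k_PE), E_s = P_s k_EP."""
    loop = k_EP * k_PE
    if loop == 1:
        raise ZeroDivisionError("singular loop: k_EP k_PE = 1")
    P_s = S / (1.0 - loop)
    return P_s, P_s * k_EP


def condition_cost(fp: ScalarFilterPoint, d: SteadyStateData,
                   include_stimulation: bool = False) -> float:
    """Squared error between the filter point's condition gains and the data."""
    E_d, P_d = _solve_dark(fp, d.H_d)
    E_p, P_p = _solve_pursuit(fp, d.T_p)
    cost = (abs(E_d - d.E_d) ** 2 + abs(P_d - d.P_d) ** 2
            + abs(E_p - d.E_p) ** 2 + abs(P_p - d.P_p) ** 2)
    if include_stimulation:
        E_s, P_s = _solve_stimulation(fp, d.S)
        cost += abs(E_s - d.E_s) ** 2 + abs(P_s - d.P_s) ** 2
    return float(cost)


def _best_fit_point(d: SteadyStateData, k_PE: complex) -> ScalarFilterPoint:
    k_EH, k_EP = closed_form_brainstem(d)
    k_PH, k_PR = degenerate_family(k_PE, d)
    return ScalarFilterPoint(k_EH=k_EH, k_EP=k_EP, k_PH=k_PH, k_PR=k_PR,
                             k_PE=k_PE)


def cost_landscape(d: SteadyStateData, axes: tuple[str, str],
                   best_fit: ScalarFilterPoint,
                   deltas1: np.ndarray, deltas2: np.ndarray,
                   reoptimize: str | None = None,
                   include_stimulation: bool = False) -> np.ndarray:
    """Cost surface over deviations of two steady-state filter values.

    `axes` names the two varied filters (e.g. ("k_PH", "k_PE")); all other
    filters stay at `best_fit` except `reoptimize`, which (if given) is
    re-optimized at every grid point — this is what exposes the flat valley
    of the Purkinje-input degeneracy.  Real steady-state slice (s = 0).
    """
    surf = np.empty((deltas1.size, deltas2.size))
    for i, d1 in enumerate(deltas1):
        for j, d2 in enumerate(deltas2):
            fp = ScalarFilterPoint(best_fit.k_EH, best_fit.k_EP,
                                   best_fit.k_PH, best_fit.k_PR,
                                   best_fit.k_PE)
            setattr(fp, axes[0], getattr(best_fit, axes[0]) + d1)
            setattr(fp, axes[1], getattr(best_fit, axes[1]) + d2)
            if reoptimize is None:
                surf[i, j] = condition_cost(fp, d, include_stimulation)
            else:
                base = float(np.real(getattr(best_fit, reoptimize)))
                span = max(1.0, abs(base)) * 10.0

                def cost_of(v: float) -> float:
                    setattr(fp, reoptimize, v)
                    try:
                        return condition_cost(fp, d, include_stimulation)
                    except ZeroDivisionError:
                        return np.inf

                res = minimize_scalar(cost_of,
                                      bounds=(base - span, base + span),
                                      method="bounded",
                                      options={"xatol": 1e-12})
                surf[i, j] = res.fun
    return surf
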
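"""The steady-state degeneracy of the Purkinje-cell input pathways.

Solves the simplified (merged-visual) circuit in closed form: the two
brainstem filters are uniquely determined by dark + pursuit condition
gains, while the three Purkinje inputs form a one-parameter affine family
of perfect fits — until a Purkinje-stimulation condition is added.
"""

import numpy as np

from vorloop import (
    ScalarFilterPoint,
    closed_form_brainstem,
    degenerate_family,
    forward_conditions,
    stimulation_response,
)
from vorloop.analytic import condition_cost

truth = ScalarFilterPoint(k_EH=1.0, k_EP=0.6, k_PH=1 / 3, k_PR=4 / 3,
                          k_PE=1 / 3)
data = forward_conditions(truth, S=1.0)
print("condition gains generated by the true circuit:")
print(f"  dark:    E_d = {data.E_d:+.3f}, P_d = {data.P_d:+.3f}")
print(f"  pursuit: E_p = {data.E_p:+.3f}, P_p = {data.P_p:+.3f}, "
      f"slip R_p = {data.R_p:+.3f}")

k_EH, k_EP = closed_form_brainstem(data)
print(f"\nbrainstem filters recovered uniquely: "
      f"k_EH = {k_EH:.6f}, k_EP = {k_EP:.6f}")

print("\ndegenerate family of Purkinje-input solutions (all cost 0):")
for k_PE in (0.0, 1 / 3, 0.8, 1.5):
    k_PH, k_PR = degenerate_family(k_PE, data)
    fp = ScalarFilterPoint(k_EH, k_EP, k_PH, k_PR, k_PE)
    print(f"  k_PE = {k_PE:.3f} -> k_PH = {k_PH:+.3f}, k_PR = {k_PR:+.3f}"
          f"   cost = {condition_cost(fp, data):.2e}")

print("\nadding the stimulation condition breaks the degeneracy:")
for k_PE in (0.0, 1 / 3, 0.8):
    k_PH, k_PR = degenerate_family(k_PE, data)
    fp = ScalarFilterPoint(k_EH, k_EP, k_PH, k_PR, k_PE)
    c = condition_cost(fp, data, include_stimulation=True)
    mark = "  <- generative parameters" if np.isclose(k_PE, 1 / 3) else ""
    print(f"  k_PE = {k_PE:.3f}   cost with stimulation = {c:.2e}{mark}")
P_s, E_s = stimulation_response(1.0, k_EP, truth.k_PE)
print(f"\nsustained stimulation response P_s = S/(1 - g) = {P_s:.3f} "
      f"(loop gain g = {k_EP * truth.k_PE:.2f})")
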
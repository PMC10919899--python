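"""Fit the closed-loop model to synthetic pre/post-learning data at one
feedback gain and report the inferred plasticity.

Runs the two-stage procedure (open-loop Tikhonov-regularized regressions,
then closed-loop fine-tuning on the dark conditions) at g = 0 and prints
the achieved learning outcomes and the net filter changes.
Takes a minute or two.
"""

import numpy as np

from vorloop import (
    RegularizationSpec,
    build_fit_dataset,
    finetune_nonvisual,
    frequency_response_dark,
    net_change,
    openloop_init,
)
from vorloop.synth import measure_step_response

dataset = build_fit_dataset(seed=0)
reg = RegularizationSpec()
g = 0.0
print(f"fitting at feedback gain g = {g} ...")
init = openloop_init(dataset, reg, g)
fit = finetune_nonvisual(init, dataset, g, reg, directions=("increase",),
                         maxiter=100)

pre = measure_step_response(fit.params_pre)
post = measure_step_response(fit.params_post["increase"])
d_norm = (post["P_ss"] - pre["P_ss"]) / 0.6
gain_pre = abs(frequency_response_dark(fit.params_pre, 0.5)["E_over_H"][0])
gain_post = abs(frequency_response_dark(fit.params_post["increase"],
                                        0.5)["E_over_H"][0])
print(f"pre-learning VOR gain:  {gain_pre:.3f}  (target 1.0)")
print(f"post-learning VOR gain: {gain_post:.3f}  (target 1.6)")
print(f"normalized Purkinje steady-state change: {d_norm:+.3f} "
      f"sp/s per deg/s per fractional gain change (target -0.65)")
print(f"net change of k_PH: {net_change(fit.delta_filter('PH')):+0.3f} "
      "(negative = net depression of the vestibular input to Purkinje "
      "cells at g = 0)")
print(f"net change of k_EH: {net_change(fit.delta_filter('EH')):+0.3f} "
      "(positive = net potentiation of the brainstem pathway)")
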
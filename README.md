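# vorloop

Closed-loop system identification for the cerebellar circuit that controls
the vestibulo-ocular reflex (VOR).

Inferring synaptic plasticity from neural recordings is confounded by
feedback: when a neuron participates in a loop, its activity can change in
the *opposite* direction from the plasticity of its inputs.  The VOR
circuit is the classic case — decades of debate over whether motor
learning depresses or potentiates the vestibular input to cerebellar
Purkinje cells turn on the unknown strength of efference-copy feedback.
`vorloop` implements a linear-temporal-filter model of this circuit that
can be fit to neural and behavioral data with the feedback strength held
at any assumed value, making the feedback-plasticity interaction explicit
and testable.

## The model

Eye velocity `E`, Purkinje-cell modulation `P`, head velocity `H`,
retinal slip `R = T - H - E`, and target velocity `T` are coupled through
causal linear filters `k_XY` (pathway to X from Y):

```
E(t) = -(H * k_EH)(t) + (P * k_EP)(t)
P(t) =  (H * k_PH)(t) + (R * k_PR)(t) + (T * k_PT)(t) + (E * k_PE)(t)
```

The efference-copy loop P → brainstem → eye command → P is positive
feedback with steady-state gain `g = Σ (k_EP * k_PE) dt`, swept from 0
("No Feedback") to 1 ("Strong Feedback").  Filters are weighted sums of
log-spaced raised-cosine basis vectors and are fit in two stages:
Tikhonov-regularized open-loop linear regressions, then closed-loop
fine-tuning against trace, frequency-response, and steady-state targets,
with a large penalty enforcing the post-learning Purkinje-modulation
change.  A companion steady-state analysis solves the simplified circuit
in closed form, exposing an exact degeneracy: the brainstem filters
(`k_EH`, `k_EP`) are uniquely determined by the data, while the three
Purkinje-input filters (`k_PH`, `k_PE`, `k_PR`) form an affine
one-parameter family of equally perfect fits

```
k_PH = (P_d - E_d k_PE) / H_d        k_PR = (P_p - k_PE E_p) / R_p
```

that only a Purkinje-stimulation condition (`P_s = S / (1 - k_EP k_PE)`)
can break.

All inputs are synthetic: `vorloop.synth` generates the 25-condition
stimulus battery (VOR in the dark, ×2, ×0/cancellation, pursuit; sines at
0.5–10 Hz, steps of 80–500 ms), noisy per-cell recordings with the full
preprocessing chain (desaccading, rate smoothing, baseline subtraction),
the 15-frequency behavioral series (0.5–50 Hz), and the printed learning
targets, from a ground-truth circuit stored alongside for
parameter-recovery tests.

## Worked example

```
$ python examples/02_degeneracy.py
condition gains generated by the true circuit:
  dark:    E_d = -1.000, P_d = +0.000
  pursuit: E_p = +0.500, P_p = +0.833, slip R_p = +0.500

brainstem filters recovered uniquely: k_EH = 1.000000, k_EP = 0.600000

degenerate family of Purkinje-input solutions (all cost 0):
  k_PE = 0.000 -> k_PH = +0.000, k_PR = +1.667   cost = 0.00e+00
  k_PE = 0.333 -> k_PH = +0.333, k_PR = +1.333   cost = 0.00e+00
  k_PE = 0.800 -> k_PH = +0.800, k_PR = +0.867   cost = 3.08e-33
  k_PE = 1.500 -> k_PH = +1.500, k_PR = +0.167   cost = 0.00e+00

adding the stimulation condition breaks the degeneracy:
  k_PE = 0.000   cost with stimulation = 8.50e-02
  k_PE = 0.333   cost with stimulation = 0.00e+00  <- generative parameters
  k_PE = 0.800   cost with stimulation = 6.16e-01

sustained stimulation response P_s = S/(1 - g) = 1.250 (loop gain g = 0.20)
```

Reading the numbers: identical dark and pursuit responses are produced by
a continuum of circuits — small vestibular input to Purkinje cells with no
efference copy, or large vestibular input offset by strong efference copy,
with the slip gain absorbing the remainder — so recording data alone
cannot localize plasticity.  The stimulation row shows the cost rising
away from the generative parameters once a perturbation condition is
added.

The other examples fit the full model: `03_fit_learning.py` reproduces the
enforced learning outcomes (post-learning VOR gain 1.6 from 1.0; Purkinje
steady-state change −0.65 sp/s per deg/s per fractional gain change) and
reports net depression of `k_PH` at g = 0 alongside net potentiation of
the brainstem pathway; `04_feedback_sweep.py` shows the inferred sign of
cerebellar plasticity flipping near g* ≈ 0.4; `05_paradox_and_stimulation.py`
reproduces the paradoxical *increase* of Purkinje activity during VOR
cancellation in both No and Strong Feedback models, decomposes it by input
pathway, and shows the transient-stimulation probe (brief 25 ms Purkinje
pulse) whose eye-velocity decay time lengthens as 1/(1−g).

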
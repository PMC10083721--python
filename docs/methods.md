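# Methods

## Model

The package treats the cytosol as the central compartment of a
one-compartment model flanked by the ER (source) and the extracellular
space (sink). After SERCA blockade with thapsigargin in the absence of
external Ca²⁺, the cytosolic balance is

    d[Ca²⁺]_cyt/dt = J_leak − J_clear

with both fluxes first order: `J_leak = k_leak·[Ca²⁺]_lER` driven by a
luminal pool that itself decays exponentially from `b[Ca²⁺]_lER`, and
`J_clear = k_clear·[Ca²⁺]_cyt`. Integration gives the Bateman equation for
the rise above baseline,

    Δ[Ca²⁺]_cyt(t) = b_lER · g · (e^{−k_leak t} − e^{−k_clear t}),
    g = k_leak/(k_clear − k_leak),

with closed-form analytics implemented alongside: peak time
`t_peak = ln(k_clear/k_leak)/(k_clear − k_leak)`, total area
`AUC = b_lER/k_clear` (independent of `k_leak`: every leaked ion is
eventually cleared), and the gain `g` that amplifies the raw
difference-of-exponentials shape.

Model assumptions worth keeping in mind: no store-operated entry (zero
external Ca²⁺ or EGTA present), no residual SERCA re-uptake, spatially
well-mixed compartments, and rate constants that are constant over the
transient. The luminal driving pool `b_lER` is a free µM-scale parameter;
it is deliberately **not** tied to the bulk ER concentration reported by a
luminal sensor (hundreds of µM) — the relation between the two is left
open, and the fit treats `b_lER` as phenomenological.

Separately measured first-order processes use the same machinery: the
clearance assay (store-operated rise interrupted with EGTA) decays as
`C(0)·e^{−k_clear t}`, and the late phase of ER depletion follows
`b_ER·e^{−k_depl t}`. Note `k_depl` (bulk store depletion) is empirically
about half of `k_leak` (the rate reconstructed from cytosolic transients);
the package keeps them as distinct quantities throughout.

## Parameters and defaults

| parameter | unit | default | role |
|---|---|---|---|
| `k_clear` | s⁻¹ | 28.34e-3 | clearance rate; fixed in Bateman fits to the clearance-assay value, identical across conditions |
| `k_leak` | s⁻¹ | fitted (control ≈ 14.55e-3) | ER leak rate; sets transient shape/duration |
| `b_lER` | µM | fitted (control ≈ 2.40) | leak-driving pool; scales amplitude |
| `k_depl` | s⁻¹ | 6.28e-3 (control) | bulk ER depletion rate, τ ≈ 159 s |
| `baseline_cyt` | µM | 0.063 | basal cytosolic Ca²⁺ |
| `b_er` | µM | 370 | basal ER Ca²⁺ |
| derivative window | samples | 5 | moving-average width before central differences |
| duration criterion | — | 5% of peak | transient end = first return within 5% of peak above baseline |

Canonical units are µM and s everywhere internally; nM appears only at
I/O with explicit unit tags (trace files carry a `unit` column; the SOCE
slope is reported in nM/s as is conventional).

Calibration constants (`K`, `R_min`, `R_max` per sensor) are
system-specific and must be supplied; the shipped
`PLACEHOLDER_FURA2`/`PLACEHOLDER_D1ER` values are generic placeholders for
simulations, not physiological calibrations. Ratios at or above `R_max`
are rejected rather than clipped, because silent clipping would flatten
peak amplitudes; callers may pre-clip explicitly.

## Estimators and numerical choices

**Exponential decay** is fit by unweighted nonlinear least squares
(lmfit/Levenberg–Marquardt) initialised from a log-linear regression; the
initialisation is exact on noiseless data, so fits are deterministic with
no random restarts.

**Depletion rate.** The depletion phase is selected automatically from the
inflection point — the post-stimulus maximum of −d[Ca²⁺]_ER/dt, which
separates the onset phase (cumulative SERCA inhibition) from free
first-order depletion — to the trace end; ties in the argmax break toward
the earliest time. The regression −dC/dt = k_depl·C + intercept uses three
numerical safeguards chosen for coarse (10 s) sampling:

1. the level is smoothed with the same moving average as the derivative,
   so the smoothing attenuation cancels in the slope;
2. the central-difference transfer function is inverted,
   `k = asinh(slope·dt)/dt`, removing the O((k·dt)²) discretisation bias
   (at k·dt ≈ 0.23 this bias alone is ~1%, enough to shift a reported
   integer time constant);
3. boundary samples and samples whose smoothing window straddles the
   inflection are excluded, since their derivative estimates mix phases
   or drop to one-sided differences.

With these, the estimator reproduces a noiseless exponential's rate to
machine precision and agrees with the direct exponential fit well within
0.5%.

**Bateman fits** hold `k_clear` fixed by default (the clearance assay
measures it independently, and one value is used across conditions);
`b_lER` and `k_leak` are then free, and `k_leak` may exceed `k_clear`.
Initialisation is deterministic: `k_leak` from the log-slope of the decay
tail (the tail reflects the slower rate) and `b_lER` from `AUC·k_clear`.
When `k_clear` is freed, the model is exactly invariant under
`(b, k₁, k₂) → (b·k₁/k₂, k₂, k₁)` — the flip-flop ambiguity — so the
solver reparameterises `k_clear = k_leak + gap` (gap ≥ 0) to pin the
labelling, and the result flags the hazard; an opt-in unconstrained search
is available. Near `k_leak = k_clear` the difference-of-exponentials form
suffers catastrophic cancellation; below a relative rate separation of
1e-6 the code switches to the analytic limit `b·k·t·e^{−kt}`
(k = mean rate), keeping the model continuous through the degenerate
point (verified to 1e-7 of the peak). The near-equal-rates regime is also
where the fit is statistically ill-conditioned: `b_lER` and `k_leak` trade
off along a ridge, so reported standard errors there are large and should
be taken seriously.

**Trace metrics.** Baseline is the mean of all pre-stimulus samples. AUC
integrates the baseline-subtracted trace clipped at zero (so noise below
baseline cannot create negative area) from the stimulus until first return
within 5% of the peak amplitude above baseline; `duration` is that
window's length. Both AUC and peak amplitude are invariant under adding a
constant offset to the trace. The SOCE slope is the OLS slope over a fixed
window after the re-addition event.

## Synthetic data

The generator emulates the study conditions: TG at 60 s, 600 s recordings,
10 s frames for dual-sensor (FURA-2 + D1ER) protocols and 3 s for
cytosol-only ones; basal cytosolic Ca²⁺ 0.063 µM and basal ER Ca²⁺ 370 µM;
additive Gaussian noise with default σ = 0.02 µM (cytosol) and 5 µM (ER),
the ER figure being a declared assumption since no per-sample noise level
is derivable from population summaries. Seeds are mandatory; identical
seeds give bit-identical traces.

The cytosolic channel is baseline plus the Bateman transient (so noiseless
fixtures match the fitted model exactly). The ER channel is held flat
before TG and then follows a logistic onset into exponential decay,

    ER(τ) = b_er · exp(−k_depl · g(τ)),
    g(τ) = w·[softplus((τ−m)/w) − softplus(−m/w)],

with midpoint m = 60 s and width w = 15 s after TG: the instantaneous
depletion rate ramps logistically from 0 to `k_depl`, modelling the
cumulative inhibition of SERCA that the pure first-order law omits, and
the analytic derivative of this model is exported as the oracle for
inflection detection. The canonical fixture triplet covers a control and
two leak-enhanced conditions (k_leak 14.55/21.03/30.07 e-3 s⁻¹, b_lER
2.40/2.38/0.62 µM, k_depl 6.28/10.14/22.51 e-3 s⁻¹); the enhanced
conditions' basal ER levels (316 and 152 µM, i.e. 85% and 41% of control)
are set to the midpoints of the observed ranges and recorded in the
manifest. A clearance-assay fixture (re-addition rise of 29.25 nM/s, EGTA
at 120 s) completes the suite.

What the generator does **not** emulate: cell-to-cell variability (one
trace = one mean cell), photobleaching and drift, sensor saturation and
buffering by the indicators, motion artefacts, and non-Gaussian shot
noise. Passing tests therefore demonstrate correctness of the estimators
under the stated noise model, not robustness to every imaging artefact.

## Phase diagram

The amplification/attenuation sweep raises `k_leak` from 8e-3 to 35e-3 s⁻¹
in 3e-3 steps (10 transients) at constant `k_clear` = 28e-3 s⁻¹. With a
constant store the peak amplitude increases monotonically in `k_leak`
(the gain term dominates) while time-to-peak shortens; with the declining
store schedule — `b_lER` falling linearly from 100% to 15% of its
reference across the grid, a linear choice made here since only the
endpoints are specified — the peaks first rise then fall, reproducing the
amplification-to-attenuation switch. Store level affects only amplitude;
transient shape is set by the rates alone.

## Problem sizes and limitations

Simulation-based tests use 600 s traces (201 samples at 3 s, 61 at 10 s),
50-point random parameter sweeps for the closed-form checks, and 60–200
noise realisations for recovery studies; these sizes give stable medians
while keeping the default suite fast. Known limitations: single-trace
analysis only (population aggregation is the caller's job); no hierarchy
or Bayesian uncertainty beyond lmfit standard errors; the depletion-phase
auto-window assumes one stimulus and a monotone post-inflection decay; and
`k_leak` is weakly identified when it approaches `k_clear` with a depleted
store (small-amplitude transients), where only the reported standard
errors convey the real uncertainty.
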
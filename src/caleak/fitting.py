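"""Parameter estimation for clearance, depletion and Bateman kinetics.

Three estimators, all deterministic (no random restarts, so fits are
reproducible without seeds) and all unweighted least squares:

* :func:`fit_exponential_decay` — C0*exp(-k t) on a decaying segment,
  e.g. the cytosolic clearance assay after EGTA (yields k_clear) or the
  late-phase ER depletion (yields k_depl).
* :func:`fit_depletion_rate` — the linear relation -d[Ca2+]_ER/dt =
  k_depl * [Ca2+]_ER over the post-inflection depletion phase; the
  rate-vs-level route to the same first-order constant.
* :func:`fit_bateman` — the two-rate transient model on a
  baseline-subtracted cytosolic transient, with the clearance rate fixed
  to its independently measured value by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy import stats

from .errors import DomainError, FitFailureError
from .kinetics import BatemanParams, bateman_transient
from .traces import Trace, _moving_average, find_inflection, smooth_derivative

__all__ = [
    "ExpDecayFit",
    "DepletionFit",
    "BatemanFit",
    "fit_exponential_decay",
    "fit_depletion_rate",
    "fit_bateman",
]


@dataclass(frozen=True)
class ExpDecayFit:
    """Exponential-decay estimate: rate k (s^-1), tau = 1/k (s), amplitude
    c0 (µM), residual rmse (µM) and the fitted time window (s)."""

    k: float
    tau: float
    c0: float
    rmse: float
    window: tuple


@dataclass(frozen=True)
class DepletionFit:
    """First-order ER depletion rate from the -dC/dt vs C regression."""

    k_depl: float
    tau_depl: float
    intercept: float  # µM/s; ~0 for a pure first-order decay
    r_squared: float
    window: tuple


@dataclass(frozen=True)
class BatemanFit:
    """Bateman-model estimate of (b_lER, k_leak[, k_clear]).

    ``flip_flop_hazard`` flags the identifiability limit of the two-rate
    model: the transient is invariant under exchanging the rate labels, so
    with k_clear free the solver constrains k_leak <= k_clear unless the
    caller opts into the flip-flop search.
    """

    params: BatemanParams
    k_clear_fixed: bool
    rmse: float
    stderr: dict
    flip_flop_hazard: bool = False


def _segment_arrays(tr: Trace):
    return tr.t - tr.t[0], tr.value


def fit_exponential_decay(tr_segment: Trace) -> ExpDecayFit:
    """Nonlinear least squares of C0*exp(-k t) on a decaying segment.

    Initialised from a log-linear regression, which is exact on noiseless
    data. Time is measured from the segment start. Raises FitFailureError
    with diagnostics if the segment does not decay (fitted k <= 0).
    """
    if tr_segment.t.size < 5:
        raise DomainError(f"need >= 5 samples, got {tr_segment.t.size}")
    if np.any(tr_segment.value <= 0):
        raise DomainError("segment values must be > 0 for an exponential fit")
    t, y = _segment_arrays(tr_segment)
    slope, logc0 = np.polyfit(t, np.log(y), 1)
    model = Model(lambda t, c0, k: c0 * np.exp(-k * t))
    params = model.make_params(c0=float(np.exp(logc0)), k=float(-slope))
    params["c0"].set(min=0.0)
    res = model.fit(y, params, t=t)
    k = float(res.params["k"].value)
    if not (res.success and k > 0):
        raise FitFailureError(
            "segment is not a decaying exponential",
            diagnostics={"k": k, "success": res.success, "message": res.message},
        )
    rmse = float(np.sqrt(np.mean(res.residual**2)))
    return ExpDecayFit(
        k=k,
        tau=1.0 / k,
        c0=float(res.params["c0"].value),
        rmse=rmse,
        window=(float(tr_segment.t[0]), float(tr_segment.t[-1])),
    )


def fit_depletion_rate(
    er_tr: Trace,
    window_mode: str = "auto",
    window: tuple | None = None,
    deriv_window: int = 5,
    stim_label: str = "TG",
) -> DepletionFit:
    """ER depletion rate from the linear -dC/dt vs C relation.

    The depletion phase is selected automatically as everything from the
    inflection time (maximum of -dC/dt after the stimulus) to the trace
    end, or explicitly via ``window=(t_start, t_end)``. A straight line
    -dC/dt = k_depl*C + intercept is fit through the phase points; a pure
    first-order decay gives intercept ~0 and r_squared ~1.

    Two discretisation corrections keep the estimate unbiased on an exact
    exponential at coarse sampling: the level is smoothed with the same
    moving average as the derivative (so the smoothing attenuation cancels
    in the ratio), and the central-difference transfer function
    sinh(k*dt)/dt is inverted to recover k from the regression slope.
    """
    deriv = smooth_derivative(er_tr, window=deriv_window)
    if window_mode == "auto":
        t_infl = find_inflection(er_tr, window=deriv_window, stim_label=stim_label).t_inflect
        # skip one smoothing half-width: samples whose moving-average
        # window straddles the inflection mix onset and decay phases
        t_start = t_infl + (deriv_window // 2 + 1) * er_tr.dt
        t_end = float(er_tr.t[-1])
    elif window_mode == "explicit":
        if window is None:
            raise DomainError("window_mode='explicit' requires window=(t_start, t_end)")
        t_start, t_end = map(float, window)
    else:
        raise DomainError(f"unknown window_mode {window_mode!r}")
    mask = (er_tr.t >= t_start) & (er_tr.t <= t_end)
    # boundary samples carry one-sided, truncated-window derivative
    # estimates of lower order; keep the regression on interior points
    edge = deriv_window // 2 + 1
    mask[:edge] = False
    mask[-edge:] = False
    if mask.sum() < 5:
        raise FitFailureError(
            f"only {int(mask.sum())} points in the depletion phase; need >= 5"
        )
    smoothed = _moving_average(er_tr.value, deriv_window) if deriv_window > 1 else er_tr.value
    c = smoothed[mask]
    y = -deriv.value[mask]
    reg = stats.linregress(c, y)
    if reg.slope <= 0:
        raise FitFailureError(
            "no first-order depletion detected (non-positive slope)",
            diagnostics={"slope": float(reg.slope), "r": float(reg.rvalue)},
        )
    dt = er_tr.dt
    k = float(np.arcsinh(reg.slope * dt) / dt)
    return DepletionFit(
        k_depl=k,
        tau_depl=1.0 / k,
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        window=(t_start, t_end),
    )


def fit_bateman(
    cyt_tr: Trace,
    k_clear: float | None = 28.34e-3,
    allow_flip_flop: bool = False,
) -> BatemanFit:
    """Fit the Bateman transient to a baseline-subtracted cytosolic trace.

    ``cyt_tr`` holds the rise above baseline with t = 0 at the stimulus.
    With ``k_clear`` given (default: the clearance-assay value measured
    separately, held identical across experimental conditions) only
    (b_lER, k_leak) are free and k_leak may take any positive value,
    including values above k_clear. With ``k_clear=None`` all three
    parameters are free; because the model is symmetric under exchanging
    the two rates, the solver then enforces k_leak <= k_clear and flags
    the identifiability hazard, unless ``allow_flip_flop=True``.

    Initialisation is deterministic: k_leak from the log-slope of the
    decay tail (the tail reflects the slower rate) and b_lER from
    auc * k_clear, the closed-form relation between total area and the
    clearance rate.
    """
    if cyt_tr.t.size < 10:
        raise DomainError(f"need >= 10 samples, got {cyt_tr.t.size}")
    t, y = _segment_arrays(cyt_tr)
    peak = float(y.max())
    if peak <= 0:
        raise FitFailureError("transient is all zero or negative; nothing to fit")

    # tail log-slope -> slower-rate estimate
    i_peak = int(np.argmax(y))
    tail_start = i_peak + max(1, (y.size - i_peak) // 3)
    tail = slice(min(tail_start, y.size - 4), y.size)
    ty, tv = t[tail], y[tail]
    pos = tv > 1e-12 * peak
    if pos.sum() >= 3:
        k_tail = float(-np.polyfit(ty[pos], np.log(tv[pos]), 1)[0])
    else:
        k_tail = np.nan
    auc = float(np.trapezoid(y, t))

    k_clear_fixed = k_clear is not None
    k_clear0 = float(k_clear) if k_clear_fixed else max(2.0 * k_tail, 1e-3)
    k_leak0 = k_tail if np.isfinite(k_tail) and k_tail > 0 else 0.5 * k_clear0
    if not k_clear_fixed and not allow_flip_flop:
        k_leak0 = min(k_leak0, 0.9 * k_clear0)
    b0 = max(auc * k_clear0, 1e-6)

    def forward(t, b_ler, k_leak, k_clear):
        return bateman_transient(t, BatemanParams(b_ler, k_leak, k_clear))

    model = Model(forward)
    params = model.make_params(b_ler=b0, k_leak=k_leak0, k_clear=k_clear0)
    params["b_ler"].set(min=1e-9)
    params["k_leak"].set(min=1e-7)
    params["k_clear"].set(min=1e-7, vary=not k_clear_fixed)
    hazard = False
    if not k_clear_fixed and not allow_flip_flop:
        # reparametrise k_clear = k_leak + gap, gap >= 0, to resolve the
        # rate-label ambiguity toward the physiological ordering
        params.add("gap", value=max(k_clear0 - k_leak0, 1e-6), min=0.0)
        params["k_clear"].set(expr="k_leak + gap")
        hazard = True
    res = model.fit(y, params, t=t)
    if not res.success:
        raise FitFailureError("Bateman fit did not converge", {"message": res.message})
    fitted = BatemanParams(
        b_ler=float(res.params["b_ler"].value),
        k_leak=float(res.params["k_leak"].value),
        k_clear=float(res.params["k_clear"].value),
    )
    stderr = {
        name: (float(p.stderr) if p.stderr is not None else float("nan"))
        for name, p in res.params.items()
        if name in ("b_ler", "k_leak", "k_clear") and p.vary
    }
    return BatemanFit(
        params=fitted,
        k_clear_fixed=k_clear_fixed,
        rmse=float(np.sqrt(np.mean(res.residual**2))),
        stderr=stderr,
        flip_flop_hazard=hazard,
    )
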
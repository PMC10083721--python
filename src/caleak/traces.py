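"""Model-free analysis of Ca2+ concentration traces.

A :class:`Trace` is one uniformly sampled channel (cytosolic or ER Ca2+,
µM) with protocol event marks (TG, IONO, Ca2+ re-addition, EGTA). The
functions here extract baseline, smoothed derivatives, the depletion
inflection point, transient summary metrics, percent store depletion and
the store-operated entry slope — all without fitting a kinetic model.

Trace files are delimited text with header ``time_s,value,unit,channel``;
values are stored internally in µM, with nM accepted/emitted only at I/O.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, MissingEventError

__all__ = [
    "Trace",
    "TransientMetrics",
    "InflectionPoint",
    "estimate_baseline",
    "smooth_derivative",
    "find_inflection",
    "transient_metrics",
    "percent_depletion",
    "soce_slope",
]

_UNIT_TO_UM = {"uM": 1.0, "µM": 1.0, "nM": 1e-3, "mM": 1e3}


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled single-channel concentration time series.

    t:       sample times in seconds, strictly increasing, uniform.
    value:   concentration in µM (internal canonical unit).
    channel: ``"cyt"`` or ``"er"``.
    events:  protocol marks as (label, time_s) pairs, e.g. ("TG", 60.0).
    """

    t: np.ndarray
    value: np.ndarray
    channel: str = "cyt"
    events: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        object.__setattr__(self, "events", tuple((str(l), float(x)) for l, x in self.events))
        if t.ndim != 1 or t.size < 2 or v.shape != t.shape:
            raise DomainError("t and value must be 1-D arrays of equal length >= 2")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise DomainError("t must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(t[-1]), 1.0):
            raise DomainError("t must be uniformly sampled")
        if not np.all(np.isfinite(v)):
            raise DomainError("values must be finite")
        for label, te in self.events:
            if te < t[0] or te > t[-1]:
                raise DomainError(f"event '{label}' at {te} s outside trace span")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def event_time(self, label: str) -> float:
        for l, te in self.events:
            if l == label:
                return te
        raise MissingEventError(
            f"event '{label}' not found; trace has {[l for l, _ in self.events]}"
        )

    def to_frame(self, unit: str = "uM") -> pd.DataFrame:
        scale = 1.0 / _UNIT_TO_UM[unit]
        return pd.DataFrame(
            {
                "time_s": self.t,
                "value": self.value * scale,
                "unit": unit,
                "channel": self.channel,
            }
        )

    def to_csv(self, path, unit: str = "uM") -> None:
        self.to_frame(unit=unit).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, events=()) -> "Trace":
        df = pd.read_csv(path)
        required = {"time_s", "value", "unit", "channel"}
        missing = required - set(df.columns)
        if missing:
            raise DomainError(f"trace file {path} missing column(s) {sorted(missing)}")
        units = df["unit"].unique()
        scale = np.array([_UNIT_TO_UM.get(u, np.nan) for u in df["unit"]])
        if np.any(np.isnan(scale)):
            raise DomainError(f"trace file {path} has unknown unit(s) {list(units)}")
        channel = str(df["channel"].iloc[0])
        return cls(
            t=df["time_s"].to_numpy(float),
            value=df["value"].to_numpy(float) * scale,
            channel=channel,
            events=tuple(events),
        )

    def with_events(self, events) -> "Trace":
        return replace(self, events=tuple(events))


@dataclass(frozen=True)
class TransientMetrics:
    """Summary of one stimulus-evoked transient.

    baseline (µM), peak_amplitude = peak rise above baseline (µM),
    t_peak measured from the stimulus (s), auc of the baseline-subtracted
    transient (µM*s), and duration of the integration window (s).
    """

    baseline: float
    peak_amplitude: float
    t_peak: float
    auc: float
    duration: float
    is_flat: bool = False

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0 or self.auc < 0 or self.duration < 0:
            raise DomainError("peak_amplitude, auc and duration must be >= 0")


@dataclass(frozen=True)
class InflectionPoint:
    """Time of maximal -d[Ca2+]_ER/dt after the stimulus, and the ER level there."""

    t_inflect: float
    ca_er_at: float


def estimate_baseline(tr: Trace, stim_label: str) -> float:
    """Mean of all samples strictly before the stimulus event (µM)."""
    t_stim = tr.event_time(stim_label)
    pre = tr.value[tr.t < t_stim]
    if pre.size < 3:
        raise DomainError(
            f"need >= 3 pre-stimulus samples to estimate baseline, got {pre.size}"
        )
    return float(pre.mean())


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    # Boundary-aware centred mean: truncated windows at the edges keep the
    # output length equal to the input length without zero-padding bias.
    kernel = np.ones(window)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def smooth_derivative(tr: Trace, window: int = 5) -> Trace:
    """Smoothed time derivative of a trace, µM/s.

    Centred moving average of ``window`` samples followed by central
    differences (one-sided at the end points); output sample times equal
    the input's. ``window`` must be odd and smaller than the trace.
    """
    if window < 1 or window % 2 == 0:
        raise DomainError(f"window must be odd and >= 1, got {window}")
    if window >= tr.t.size:
        raise DomainError(f"window {window} too large for trace of {tr.t.size} samples")
    smoothed = _moving_average(tr.value, window) if window > 1 else tr.value
    deriv = np.gradient(smoothed, tr.t)
    return Trace(t=tr.t, value=deriv, channel=tr.channel, events=tr.events)


def find_inflection(
    er_tr: Trace, window: int = 5, stim_label: str = "TG"
) -> InflectionPoint:
    """Locate the inflection of ER depletion after the stimulus.

    The time at which -d[Ca2+]_ER/dt is maximal divides the response into
    the onset phase (cumulative SERCA inhibition) and the late phase of
    pure first-order depletion; the exponential depletion fit starts
    there. Ties are broken toward the earliest time.
    """
    t_stim = er_tr.event_time(stim_label)
    deriv = smooth_derivative(er_tr, window=window)
    mask = er_tr.t > t_stim
    if not np.any(mask):
        raise DomainError("no post-stimulus samples")
    neg = -deriv.value[mask]
    if np.ptp(neg) < 1e-15 * max(1.0, np.max(np.abs(er_tr.value))):
        raise DomainError(
            "derivative is constant after the stimulus; inflection undefined"
        )
    i = int(np.argmax(neg))  # argmax returns the earliest maximum
    t_sel = er_tr.t[mask]
    return InflectionPoint(
        t_inflect=float(t_sel[i]), ca_er_at=float(er_tr.value[mask][i])
    )


def transient_metrics(
    tr: Trace, stim_label: str, full_support: bool = False
) -> TransientMetrics:
    """Baseline, peak amplitude, time-to-peak, AUC and duration.

    The AUC integrates the baseline-subtracted trace (clipped at zero so
    noise below baseline cannot produce negative area) from the stimulus
    until the trace first returns within 5% of the peak amplitude above
    baseline, or to the trace end; ``duration`` is the length of that
    window. ``full_support=True`` instead integrates to the trace end
    regardless of the return criterion. A trace that never rises above
    baseline yields zero metrics with ``is_flat=True`` and a warning.
    """
    baseline = estimate_baseline(tr, stim_label)
    t_stim = tr.event_time(stim_label)
    mask = tr.t >= t_stim
    t_post = tr.t[mask]
    delta = np.clip(tr.value[mask] - baseline, 0.0, None)
    peak_amplitude = float(delta.max())
    # guard against pure rounding residue of the baseline subtraction
    if peak_amplitude <= 1e-12 * max(1.0, abs(baseline)):
        warnings.warn("trace never rises above baseline; returning zero metrics")
        return TransientMetrics(baseline, 0.0, 0.0, 0.0, 0.0, is_flat=True)
    i_peak = int(np.argmax(delta))
    # integration window: stimulus -> first return within 5% of peak
    if full_support:
        i_end = delta.size - 1
    else:
        below = np.flatnonzero(delta[i_peak:] <= 0.05 * peak_amplitude)
        i_end = i_peak + int(below[0]) if below.size else delta.size - 1
    auc = float(np.trapezoid(delta[: i_end + 1], t_post[: i_end + 1]))
    return TransientMetrics(
        baseline=baseline,
        peak_amplitude=peak_amplitude,
        t_peak=float(t_post[i_peak] - t_stim),
        auc=auc,
        duration=float(t_post[i_end] - t_stim),
    )


def percent_depletion(b_er: float, ca_er: float) -> float:
    """Percent loss of ER Ca2+ relative to the basal level b_er."""
    if not b_er > 0:
        raise DomainError(f"basal ER Ca2+ must be > 0, got {b_er}")
    if ca_er < 0 or ca_er > b_er:
        raise DomainError(f"need 0 <= ca_er <= b_er, got ca_er={ca_er}, b_er={b_er}")
    return 100.0 * (b_er - ca_er) / b_er


def soce_slope(tr: Trace, readd_label: str = "Ca", fit_window: float = 60.0) -> float:
    """Initial rate of cytosolic Ca2+ rise after Ca2+ re-addition, nM/s.

    Least-squares slope of the trace over [t_readd, t_readd + fit_window];
    the empirical measure of store-operated Ca2+ entry.
    """
    t0 = tr.event_time(readd_label)
    if t0 + fit_window > tr.t[-1] + 0.5 * tr.dt:
        raise DomainError(
            f"fit window [{t0}, {t0 + fit_window}] s exceeds trace end {tr.t[-1]} s"
        )
    mask = (tr.t >= t0) & (tr.t <= t0 + fit_window)
    if mask.sum() < 3:
        raise DomainError(f"need >= 3 samples in the fit window, got {int(mask.sum())}")
    slope_um_per_s = np.polyfit(tr.t[mask], tr.value[mask], 1)[0]
    return float(slope_um_per_s * 1e3)
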
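"""Closed-form kinetics of the one-compartment Ca2+ transient model.

After SERCA blockade by thapsigargin, and with external Ca2+ chelated, the
cytosol exchanges Ca2+ with only two first-order pathways: a leak out of
the ER lumen (rate ``k_leak``, driven by the near-membrane luminal pool
``b_lER``) and clearance across the plasma membrane (rate ``k_clear``).
The resulting change of cytosolic Ca2+ above baseline is the Bateman
equation — the classic difference-of-exponentials solution of sequential
first-order input/output:

    dCa(t) = b_lER * k_leak/(k_clear - k_leak)
             * (exp(-k_leak*t) - exp(-k_clear*t))

This module provides the forward model, its term-by-term breakdown, its
closed-form analytics (peak time, peak, AUC, gain), and the phase-diagram
sweep that maps amplification vs. attenuation of transients as the leak
rate rises while the ER Ca2+ content falls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateRatesError, DomainError

__all__ = [
    "EQUAL_RATE_REL_TOL",
    "BatemanParams",
    "BatemanComponents",
    "BatemanAnalytics",
    "PhaseDiagramSpec",
    "rate_to_tau",
    "exponential_decay",
    "first_order_flux",
    "bateman_transient",
    "bateman_components",
    "bateman_analytics",
    "phase_diagram",
    "declining_b_ler_schedule",
]

# Relative rate separation below which the difference-of-exponentials form
# is abandoned for the equal-rate limit b_lER*k*t*exp(-k*t). Below ~1e-6
# the cancellation error in (e^{-k1 t} - e^{-k2 t}) exceeds the error of
# the limit form.
EQUAL_RATE_REL_TOL = 1e-6


def rate_to_tau(k: float) -> float:
    """Time constant tau = 1/k (s) of a first-order rate k (s^-1)."""
    if not k > 0:
        raise DomainError(f"rate must be > 0, got {k}")
    return 1.0 / k


def exponential_decay(t, c0: float, k: float):
    """First-order decay ``c0 * exp(-k t)``.

    Describes both the cytosolic clearance transient after interrupting
    store-operated entry and the ER depletion time course after the leak
    is fully unmasked. ``t`` may be scalar or array (seconds); ``c0`` in
    µM, ``k`` in s^-1.
    """
    if not k > 0:
        raise DomainError(f"decay rate must be > 0, got {k}")
    if c0 < 0:
        raise DomainError(f"initial concentration must be >= 0, got {c0}")
    t_arr = np.asarray(t, dtype=float)
    out = c0 * np.exp(-k * t_arr)
    return out if t_arr.ndim else float(out)


def first_order_flux(k: float, c: float) -> float:
    """First-order flux J = k*C in µM/s.

    With C = luminal ER Ca2+ this is the leak flux J_leak; with C =
    cytosolic Ca2+ it is the clearance flux J_clear.
    """
    if k < 0 or c < 0:
        raise DomainError(f"rate and concentration must be >= 0, got k={k}, C={c}")
    return k * c


@dataclass(frozen=True)
class BatemanParams:
    """Parameters of the Bateman transient.

    b_ler:  leak-driving luminal Ca2+ pool b[Ca2+]_lER, µM. A free fit
            parameter on the µM scale; not constrained to equal the
            bulk ER concentration measured by the luminal sensor.
    k_leak: ER Ca2+ leak rate, s^-1.
    k_clear: cytosolic Ca2+ clearance rate, s^-1.
    """

    b_ler: float
    k_leak: float
    k_clear: float

    def __post_init__(self) -> None:
        for name in ("b_ler", "k_leak", "k_clear"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise DomainError(f"{name} must be finite and > 0, got {v}")

    @property
    def is_degenerate(self) -> bool:
        """True when the two rates are equal within EQUAL_RATE_REL_TOL."""
        return abs(self.k_clear - self.k_leak) < EQUAL_RATE_REL_TOL * self.k_clear

    @property
    def gain(self) -> float:
        """Amplitude gain k_leak/(k_clear - k_leak); pole at equal rates."""
        if self.is_degenerate:
            raise DegenerateRatesError(
                f"gain undefined at k_leak == k_clear (= {self.k_leak:g} s^-1)"
            )
        return self.k_leak / (self.k_clear - self.k_leak)


def bateman_transient(t, p: BatemanParams):
    """Cytosolic Ca2+ rise above baseline, µM, at time(s) t >= 0 (s).

    Difference-of-exponentials form, switching to the analytic equal-rate
    limit ``b_lER * k t exp(-k t)`` (k = mean of the two rates) when the
    rates are closer than EQUAL_RATE_REL_TOL.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    if p.is_degenerate:
        k = 0.5 * (p.k_leak + p.k_clear)
        out = p.b_ler * k * t_arr * np.exp(-k * t_arr)
    else:
        out = p.b_ler * p.gain * (np.exp(-p.k_leak * t_arr) - np.exp(-p.k_clear * t_arr))
    return out if t_arr.ndim else float(out)


@dataclass(frozen=True)
class BatemanComponents:
    """Term-by-term breakdown of the Bateman equation.

    fa = exp(-k_leak t)        decay of the luminal driving pool
    fb = exp(-k_clear t)       clearance exponential
    fc = fa - fb               unscaled transient shape
    fd = gain * fc             shape scaled by k_leak/(k_clear-k_leak);
                               b_lER * fd is the modelled transient
    """

    t: np.ndarray
    fa: np.ndarray
    fb: np.ndarray
    fc: np.ndarray
    fd: np.ndarray
    gain: float


def bateman_components(t, p: BatemanParams) -> BatemanComponents:
    """Break the transient into its single terms (see Fig.-style analysis).

    Raises DegenerateRatesError at equal rates, where the gain term has an
    asymptote and the breakdown is undefined.
    """
    gain = p.gain  # raises on degenerate rates
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise DomainError("t must be >= 0")
    fa = np.exp(-p.k_leak * t_arr)
    fb = np.exp(-p.k_clear * t_arr)
    fc = fa - fb
    return BatemanComponents(t=t_arr, fa=fa, fb=fb, fc=fc, fd=gain * fc, gain=gain)


@dataclass(frozen=True)
class BatemanAnalytics:
    """Closed-form summary of a Bateman transient."""

    t_peak: float  # s
    peak: float  # µM
    auc: float  # µM*s, integral over [0, inf)
    gain: float  # dimensionless; +/-inf flag at equal rates not stored


def bateman_analytics(p: BatemanParams) -> BatemanAnalytics:
    """Peak time, peak amplitude, total AUC and gain of the transient.

    t_peak = ln(k_clear/k_leak)/(k_clear - k_leak) (1/k at equal rates);
    auc = b_lER/k_clear, the exact integral of the transient over all t.
    Note the AUC does not involve k_leak: every leaked ion is eventually
    cleared, so the time-integrated exposure is set by clearance alone.
    """
    if p.is_degenerate:
        k = 0.5 * (p.k_leak + p.k_clear)
        t_peak = 1.0 / k
        gain = math.inf
    else:
        t_peak = math.log(p.k_clear / p.k_leak) / (p.k_clear - p.k_leak)
        gain = p.gain
    peak = bateman_transient(t_peak, p)
    return BatemanAnalytics(t_peak=t_peak, peak=peak, auc=p.b_ler / p.k_clear, gain=gain)


@dataclass(frozen=True)
class PhaseDiagramSpec:
    """Sweep of leak rates (and luminal pools) at fixed clearance.

    k_leak_grid: leak rates, s^-1, one transient per grid point.
    b_ler_grid:  luminal pool per grid point, µM. A single value is
                 broadcast (constant-store sweep); otherwise must match
                 k_leak_grid in length (e.g. a declining-store schedule).
    k_clear:     clearance rate, s^-1, held constant across the sweep.
    t:           simulation time grid, s (default 0-600 s at 1 s).
    """

    k_leak_grid: tuple
    b_ler_grid: tuple
    k_clear: float
    t: np.ndarray = field(default_factory=lambda: np.arange(0.0, 601.0, 1.0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_leak_grid", tuple(float(k) for k in self.k_leak_grid))
        object.__setattr__(self, "b_ler_grid", tuple(float(b) for b in self.b_ler_grid))
        if not self.k_leak_grid or not self.b_ler_grid:
            raise DomainError("grids must be non-empty")
        if any(k <= 0 for k in self.k_leak_grid) or any(b <= 0 for b in self.b_ler_grid):
            raise DomainError("grid values must be strictly positive")
        if not self.k_clear > 0:
            raise DomainError(f"k_clear must be > 0, got {self.k_clear}")
        if len(self.b_ler_grid) not in (1, len(self.k_leak_grid)):
            raise DomainError(
                "b_ler_grid must have length 1 or match k_leak_grid "
                f"({len(self.b_ler_grid)} vs {len(self.k_leak_grid)})"
            )


def declining_b_ler_schedule(
    n: int, reference: float, start_frac: float = 1.0, end_frac: float = 0.15
) -> tuple:
    """Linear decline of the luminal pool across an n-point leak sweep.

    Models the progressive ER Ca2+ loss that accompanies an increasing
    leak: the pool falls linearly from start_frac to end_frac of the
    reference value (defaults 100% -> 15%).
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    fracs = np.linspace(start_frac, end_frac, n)
    return tuple(reference * fracs)


def phase_diagram(spec: PhaseDiagramSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one transient per (k_leak, b_lER) pair.

    Returns ``(transients, metrics)``: a long-format table with columns
    (k_leak, b_ler, t, delta_ca_cyt) and a per-transient metrics table
    with analytic t_peak, peak, auc and gain. With a constant b_lER the
    peaks rise monotonically with k_leak (amplification); with a declining
    schedule the peaks first rise then fall (amplification -> attenuation
    switch), while t_peak shortens throughout.
    """
    b_grid = spec.b_ler_grid
    if len(b_grid) == 1:
        b_grid = b_grid * len(spec.k_leak_grid)
    frames = []
    rows = []
    for k_leak, b_ler in zip(spec.k_leak_grid, b_grid):
        p = BatemanParams(b_ler=b_ler, k_leak=k_leak, k_clear=spec.k_clear)
        y = bateman_transient(spec.t, p)
        frames.append(
            pd.DataFrame(
                {"k_leak": k_leak, "b_ler": b_ler, "t": spec.t, "delta_ca_cyt": y}
            )
        )
        a = bateman_analytics(p)
        rows.append(
            {
                "k_leak": k_leak,
                "b_ler": b_ler,
                "t_peak": a.t_peak,
                "peak": a.peak,
                "auc": a.auc,
                "gain": a.gain,
            }
        )
    return pd.concat(frames, ignore_index=True), pd.DataFrame(rows)
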
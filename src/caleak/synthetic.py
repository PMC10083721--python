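"""Synthetic paired cytosolic/ER Ca2+ traces under standard protocols.

No public imaging data accompany the kinetic analysis this package
implements, so every pipeline stage is exercised on traces generated
here. The generator is the forward model plus protocol structure:

* cytosolic channel — baseline plus a Bateman transient starting at the
  TG event (store-release protocols), a linear store-operated entry ramp
  (re-addition protocol), or ramp-then-exponential-clearance (clearance
  assay);
* ER channel — basal level held flat before TG, then a logistic onset
  (modelling cumulative SERCA inhibition, which the pure first-order
  depletion law omits) blending into an exponential decay at the
  depletion rate k_depl.

Gaussian noise is added independently per channel and sample from a
seeded generator; identical seeds give bit-identical traces. Sampling
defaults follow the imaging protocols: 3 s frames for cytosol-only
recordings, 10 s for dual-sensor recordings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .calibration import CalibrationParams, concentration_to_ratio
from .errors import DomainError
from .kinetics import BatemanParams, bateman_transient
from .traces import Trace

__all__ = [
    "DUAL_SENSOR_DT",
    "CYTOSOL_ONLY_DT",
    "ProtocolSpec",
    "GroundTruth",
    "ExperimentData",
    "er_depletion_model",
    "er_depletion_derivative",
    "generate_experiment",
    "fixture_suite",
    "CONTROL_TRUTH",
]

DUAL_SENSOR_DT = 10.0  # s, simultaneous FURA-2 + D1ER imaging
CYTOSOL_ONLY_DT = 3.0  # s, FURA-2 alone

_DUAL_PROTOCOLS = {"tg_zero_ca", "tg_with_ca", "tg_then_iono", "puro_pretreat"}
_CYT_ONLY_PROTOCOLS = {"iono", "ca_readdition", "clearance_assay"}


@dataclass(frozen=True)
class ProtocolSpec:
    """One recording protocol: events, sampling, duration, noise, seed."""

    protocol_id: str
    events: tuple
    sampling_dt: float | None = None
    duration: float = 600.0
    noise_sd_cyt: float = 0.02  # µM
    noise_sd_er: float = 5.0  # µM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol_id not in _DUAL_PROTOCOLS | _CYT_ONLY_PROTOCOLS:
            raise DomainError(f"unknown protocol_id {self.protocol_id!r}")
        object.__setattr__(self, "events", tuple((str(l), float(t)) for l, t in self.events))
        if self.sampling_dt is None:
            dt = DUAL_SENSOR_DT if self.is_dual_sensor else CYTOSOL_ONLY_DT
            object.__setattr__(self, "sampling_dt", dt)
        if not self.sampling_dt > 0:
            raise DomainError("sampling_dt must be > 0")
        if self.noise_sd_cyt < 0 or self.noise_sd_er < 0:
            raise DomainError("noise SDs must be >= 0")
        if self.events and self.duration < max(t for _, t in self.events):
            raise DomainError("duration must cover all protocol events")

    @property
    def is_dual_sensor(self) -> bool:
        return self.protocol_id in _DUAL_PROTOCOLS

    def event_time(self, label: str) -> float:
        for l, t in self.events:
            if l == label:
                return t
        raise DomainError(f"protocol {self.protocol_id!r} lacks required event {label!r}")


@dataclass(frozen=True)
class GroundTruth:
    """True generator parameters, echoed alongside every experiment.

    Units: concentrations µM, rates s^-1, times s, soce_slope nM/s.
    ``onset_midpoint``/``onset_width`` shape the logistic onset of ER
    depletion, measured from the TG event.
    """

    bateman: BatemanParams
    k_depl: float = 6.28e-3
    baseline_cyt: float = 0.063
    b_er: float = 370.0
    onset_midpoint: float = 60.0
    onset_width: float = 15.0
    soce_slope: float | None = None  # nM/s
    iono_bateman: BatemanParams | None = None

    def __post_init__(self) -> None:
        for name in ("k_depl", "baseline_cyt", "b_er", "onset_midpoint", "onset_width"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")
        if self.soce_slope is not None and not self.soce_slope > 0:
            raise DomainError("soce_slope must be > 0 when given")


#: Control-condition parameters: Bateman reconstruction values of the
#: control transient, control depletion rate, and basal levels.
CONTROL_TRUTH = GroundTruth(
    bateman=BatemanParams(b_ler=2.40, k_leak=14.55e-3, k_clear=28.34e-3),
    k_depl=6.28e-3,
    baseline_cyt=0.063,
    b_er=370.0,
)


@dataclass(frozen=True)
class ExperimentData:
    cyt: Trace
    er: Trace | None
    truth: GroundTruth
    protocol: ProtocolSpec

    def as_ratios(
        self, cal_cyt: CalibrationParams, cal_er: CalibrationParams | None = None
    ) -> tuple:
        """Pass concentrations through the inverse calibration (ratio mode)."""
        r_cyt = concentration_to_ratio(self.cyt.value, cal_cyt)
        r_er = None
        if self.er is not None:
            if cal_er is None:
                raise DomainError("cal_er required for a dual-sensor experiment")
            r_er = concentration_to_ratio(self.er.value, cal_er)
        return r_cyt, r_er


def _softplus(x):
    return np.logaddexp(0.0, x)


def er_depletion_model(tau, truth: GroundTruth):
    """ER Ca2+ (µM) at time tau >= 0 after TG: logistic onset into decay.

    The instantaneous depletion rate ramps from 0 to k_depl along a
    logistic switch s(tau) (midpoint m, width w), modelling cumulative
    SERCA inhibition; integrating the switch gives

        ER(tau) = b_er * exp(-k_depl * g(tau)),
        g(tau) = w*[softplus((tau-m)/w) - softplus(-m/w)]

    so the trace is flat early (g ~ 0) and purely exponential with rate
    k_depl once the switch saturates.
    """
    tau = np.asarray(tau, dtype=float)
    m, w = truth.onset_midpoint, truth.onset_width
    g = w * (_softplus((tau - m) / w) - _softplus(-m / w))
    return truth.b_er * np.exp(-truth.k_depl * g)


def er_depletion_derivative(tau, truth: GroundTruth):
    """Analytic d[Ca2+]_ER/dtau of the onset-into-decay model (µM/s).

    Equals -k_depl * s(tau) * ER(tau) with the logistic switch s; its
    (negated) maximum is the generator's true inflection point, used as
    the oracle for inflection detection.
    """
    tau = np.asarray(tau, dtype=float)
    m, w = truth.onset_midpoint, truth.onset_width
    s = 1.0 / (1.0 + np.exp(-(tau - m) / w))
    return -truth.k_depl * s * er_depletion_model(tau, truth)


def _cyt_model(t: np.ndarray, proto: ProtocolSpec, truth: GroundTruth) -> np.ndarray:
    base = np.full_like(t, truth.baseline_cyt)
    pid = proto.protocol_id
    if pid in {"tg_zero_ca", "tg_with_ca", "puro_pretreat", "tg_then_iono"}:
        t_tg = proto.event_time("TG")
        tau = t - t_tg
        m = tau >= 0
        base[m] += bateman_transient(tau[m], truth.bateman)
        if pid == "tg_then_iono":
            if truth.iono_bateman is None:
                raise DomainError("tg_then_iono requires truth.iono_bateman")
            t_io = proto.event_time("IONO")
            tau = t - t_io
            m = tau >= 0
            base[m] += bateman_transient(tau[m], truth.iono_bateman)
    elif pid == "iono":
        if truth.iono_bateman is None:
            raise DomainError("iono protocol requires truth.iono_bateman")
        t_io = proto.event_time("IONO")
        tau = t - t_io
        m = tau >= 0
        base[m] += bateman_transient(tau[m], truth.iono_bateman)
    elif pid == "ca_readdition":
        if truth.soce_slope is None:
            raise DomainError("ca_readdition requires truth.soce_slope")
        t_ca = proto.event_time("Ca")
        tau = np.clip(t - t_ca, 0.0, None)
        base += truth.soce_slope * 1e-3 * tau  # nM/s -> µM/s
    elif pid == "clearance_assay":
        if truth.soce_slope is None:
            raise DomainError("clearance_assay requires truth.soce_slope")
        t_ca = proto.event_time("Ca")
        t_eg = proto.event_time("EGTA")
        if t_eg <= t_ca:
            raise DomainError("EGTA event must follow the Ca re-addition event")
        rise = truth.soce_slope * 1e-3 * np.clip(t - t_ca, 0.0, None)
        peak_rise = truth.soce_slope * 1e-3 * (t_eg - t_ca)
        after = t >= t_eg
        base += rise
        base[after] = truth.baseline_cyt + peak_rise * np.exp(
            -truth.bateman.k_clear * (t[after] - t_eg)
        )
    return base


def generate_experiment(proto: ProtocolSpec, truth: GroundTruth) -> ExperimentData:
    """Simulate one experiment; identical seed implies identical output.

    Store-release protocols return paired cytosolic and ER traces; the
    cytosol-only protocols (iono, ca_readdition, clearance_assay) return
    ``er=None``.
    """
    n = int(round(proto.duration / proto.sampling_dt)) + 1
    t = np.arange(n, dtype=float) * proto.sampling_dt
    rng = np.random.default_rng(proto.seed)

    cyt_values = _cyt_model(t, proto, truth)
    if proto.noise_sd_cyt > 0:
        cyt_values = cyt_values + rng.normal(0.0, proto.noise_sd_cyt, size=n)
    cyt = Trace(t=t, value=cyt_values, channel="cyt", events=proto.events)

    er = None
    if proto.is_dual_sensor:
        t_tg = proto.event_time("TG")
        er_values = np.full_like(t, truth.b_er)
        m = t >= t_tg
        er_values[m] = er_depletion_model(t[m] - t_tg, truth)
        if proto.noise_sd_er > 0:
            er_values = er_values + rng.normal(0.0, proto.noise_sd_er, size=n)
        er = Trace(t=t, value=er_values, channel="er", events=proto.events)
    return ExperimentData(cyt=cyt, er=er, truth=truth, protocol=proto)


# ---------------------------------------------------------------------------
# canonical fixtures


def _truth_dict(truth: GroundTruth) -> dict:
    d = {
        "b_ler_uM": truth.bateman.b_ler,
        "k_leak_per_s": truth.bateman.k_leak,
        "k_clear_per_s": truth.bateman.k_clear,
        "k_depl_per_s": truth.k_depl,
        "baseline_cyt_uM": truth.baseline_cyt,
        "b_er_uM": truth.b_er,
        "onset_midpoint_s": truth.onset_midpoint,
        "onset_width_s": truth.onset_width,
    }
    if truth.soce_slope is not None:
        d["soce_slope_nM_per_s"] = truth.soce_slope
    return d


#: The three store-release conditions: a control plus two leak-enhanced
#: states with progressively faster leak/depletion and, at the strongest
#: enhancement, a depleted driving pool. The basal ER levels for the
#: enhanced states (declared assumptions) sit at 85% and 41% of control,
#: the midpoints of the observed ranges.
FIXTURE_CONDITIONS = {
    "control": GroundTruth(
        bateman=BatemanParams(2.40, 14.55e-3, 28.34e-3), k_depl=6.28e-3, b_er=370.0
    ),
    "leak_enhanced_mid": GroundTruth(
        bateman=BatemanParams(2.38, 21.03e-3, 28.34e-3), k_depl=10.14e-3, b_er=316.0
    ),
    "leak_enhanced_high": GroundTruth(
        bateman=BatemanParams(0.62, 30.07e-3, 28.34e-3), k_depl=22.51e-3, b_er=152.0
    ),
}

_CLEARANCE_TRUTH = GroundTruth(
    bateman=BatemanParams(2.40, 14.55e-3, 28.34e-3),
    k_depl=6.28e-3,
    soce_slope=29.25,
)


def fixture_suite(out_dir, base_seed: int = 101) -> dict:
    """Write the canonical trace fixtures and their ground-truth manifest.

    Three paired (cyt+ER) store-release fixtures — control and two
    leak-enhanced conditions — plus one clearance-assay fixture, each in
    a noisy and a noiseless variant. Returns the manifest dict, also
    written as ``manifest.yaml``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"fixtures": {}}

    for i, (name, truth) in enumerate(FIXTURE_CONDITIONS.items()):
        entry = {"protocol": "tg_zero_ca", "truth": _truth_dict(truth), "files": {}}
        for variant, sd_c, sd_e in (("noisy", 0.02, 5.0), ("noiseless", 0.0, 0.0)):
            proto = ProtocolSpec(
                protocol_id="tg_zero_ca",
                events=(("TG", 60.0),),
                duration=600.0,
                noise_sd_cyt=sd_c,
                noise_sd_er=sd_e,
                seed=base_seed + i,
            )
            exp = generate_experiment(proto, truth)
            for ch, tr in (("cyt", exp.cyt), ("er", exp.er)):
                fname = f"{name}_{variant}_{ch}.csv"
                tr.to_csv(out / fname)
                entry["files"][f"{variant}_{ch}"] = fname
            entry.setdefault("noise", {})[variant] = {"sd_cyt_uM": sd_c, "sd_er_uM": sd_e}
            entry.setdefault("seed", proto.seed)
            entry["events"] = [list(e) for e in proto.events]
        manifest["fixtures"][name] = entry

    entry = {"protocol": "clearance_assay", "truth": _truth_dict(_CLEARANCE_TRUTH), "files": {}}
    for variant, sd_c in (("noisy", 0.02), ("noiseless", 0.0)):
        proto = ProtocolSpec(
            protocol_id="clearance_assay",
            events=(("Ca", 60.0), ("EGTA", 120.0)),
            duration=400.0,
            noise_sd_cyt=sd_c,
            seed=base_seed + 10,
        )
        exp = generate_experiment(proto, _CLEARANCE_TRUTH)
        fname = f"clearance_{variant}_cyt.csv"
        exp.cyt.to_csv(out / fname)
        entry["files"][f"{variant}_cyt"] = fname
        entry.setdefault("noise", {})[variant] = {"sd_cyt_uM": sd_c}
        entry.setdefault("seed", proto.seed)
        entry["events"] = [list(e) for e in proto.events]
    manifest["fixtures"]["clearance"] = entry

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
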
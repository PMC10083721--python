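import math

import numpy as np
import pytest

from caleak import (
    BatemanParams,
    PhaseDiagramSpec,
    bateman_analytics,
    bateman_components,
    bateman_transient,
    declining_b_ler_schedule,
    exponential_decay,
    first_order_flux,
    phase_diagram,
    rate_to_tau,
)
from caleak.errors import DegenerateRatesError, DomainError

from conftest import CONTROL


class TestExponentialDecay:
    def test_initial_value_and_efolding(self):
        assert exponential_decay(0.0, 0.5, 28.34e-3) == pytest.approx(0.5)
        k = 6.06e-3
        tau = rate_to_tau(k)
        assert tau == pytest.approx(165.0, abs=0.5)  # the control depletion time constant
        assert exponential_decay(tau, 1.0, k) == pytest.approx(1 / math.e)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(DomainError):
            exponential_decay(1.0, 1.0, 0.0)
        with pytest.raises(DomainError):
            rate_to_tau(-1.0)


class TestFirstOrderFlux:
    @pytest.mark.parametrize(
        "k, c, expected",
        [
            (21e-3, 370.0, 7.77),  # leak flux at basal ER Ca2+, µM/s
            (28.34e-3, 0.45, 0.012753),  # clearance flux at mid cytosolic Ca2+
            (0.0, 5.0, 0.0),
        ],
    )
    def test_values(self, k, c, expected):
        assert first_order_flux(k, c) == pytest.approx(expected, rel=1e-9)

    def test_rejects_negative_inputs(self):
        with pytest.raises(DomainError):
            first_order_flux(-1e-3, 1.0)
        with pytest.raises(DomainError):
            first_order_flux(1e-3, -1.0)


class TestBatemanTransient:
    def test_zero_at_time_zero(self):
        assert bateman_transient(0.0, CONTROL) == 0.0

    def test_peak_matches_dense_grid_argmax(self):
        # independent oracle: dense-grid argmax at dt = 0.01 s
        t = np.arange(0.0, 600.0, 0.01)
        y = bateman_transient(t, CONTROL)
        i = int(np.argmax(y))
        a = bateman_analytics(CONTROL)
        assert abs(a.t_peak - t[i]) <= 0.01
        assert a.peak == pytest.approx(y[i], rel=1e-6)
        # headline control values: peak ~0.61 µM at ~48 s
        assert a.peak == pytest.approx(0.610, abs=0.001)
        assert a.t_peak == pytest.approx(48.4, abs=0.1)

    def test_equal_rate_limit_peak(self):
        k = 20e-3
        p = BatemanParams(b_ler=2.0, k_leak=k, k_clear=k)
        assert bateman_transient(1.0 / k, p) == pytest.approx(2.0 / math.e, rel=1e-12)
        a = bateman_analytics(p)
        assert a.t_peak == pytest.approx(1.0 / k)
        assert a.peak == pytest.approx(2.0 / math.e)

    def test_nonnegative_and_vanishing(self):
        t = np.linspace(0, 5000, 2000)
        y = bateman_transient(t, CONTROL)
        assert np.all(y >= 0)
        assert y[-1] < 1e-12

    def test_rate_exchange_reparameterisation(self):
        """Swapping the two rates while rescaling the driving pool by
        k_leak/k_clear leaves the curve unchanged — the flip-flop
        identifiability hazard: (b, k1, k2) and (b*k1/k2, k2, k1) are
        indistinguishable from the transient alone."""
        t = np.linspace(0, 600, 301)
        k1, k2 = 10e-3, 30e-3
        a = bateman_transient(t, BatemanParams(1.0, k1, k2))
        b = bateman_transient(t, BatemanParams(k1 / k2, k2, k1))
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_degenerate_limit_continuity(self):
        k = 25e-3
        t = np.linspace(0, 400, 801)
        limit = bateman_transient(t, BatemanParams(1.0, k, k))
        peak = limit.max()
        for sign in (+1, -1):
            near = bateman_transient(t, BatemanParams(1.0, k, k * (1 + sign * 1e-9)))
            assert np.max(np.abs(near - limit)) < 1e-7 * peak


class TestBatemanComponents:
    def test_unity_at_time_zero(self):
        c = bateman_components(0.0, CONTROL)
        assert c.fa[0] == 1.0 and c.fb[0] == 1.0
        assert c.fc[0] == 0.0 and c.fd[0] == 0.0

    def test_control_gain(self):
        c = bateman_components(0.0, CONTROL)
        assert c.gain == pytest.approx(0.01455 / (0.02834 - 0.01455), rel=1e-12)
        assert c.gain == pytest.approx(1.0551, abs=1e-4)

    def test_scaled_shape_equals_transient(self):
        t = np.linspace(0, 600, 601)
        c = bateman_components(t, CONTROL)
        nz = c.fc != 0
        np.testing.assert_allclose(c.fd[nz] / c.fc[nz], c.gain, rtol=1e-12)
        np.testing.assert_allclose(
            CONTROL.b_ler * c.fd, bateman_transient(t, CONTROL), rtol=1e-12
        )

    def test_degenerate_rates_raise(self):
        with pytest.raises(DegenerateRatesError):
            bateman_components(10.0, BatemanParams(1.0, 20e-3, 20e-3))


class TestBatemanAnalytics:
    def test_auc_closed_form_vs_numeric(self):
        a = bateman_analytics(CONTROL)
        assert a.auc == pytest.approx(2.40 / 0.02834, rel=1e-12)
        t = np.arange(0.0, 20.0 / CONTROL.k_leak, 0.05)
        numeric = np.trapezoid(bateman_transient(t, CONTROL), t)
        assert a.auc == pytest.approx(numeric, rel=1e-6)

    def test_auc_property_random_parameter_sets(self):
        """Closed form b_lER/k_clear matches trapezoid integration within
        1e-5 relative on 50 random parameter sets."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = BatemanParams(
                b_ler=rng.uniform(0.1, 10.0),
                k_leak=rng.uniform(2e-3, 50e-3),
                k_clear=rng.uniform(2e-3, 50e-3),
            )
            tmax = 25.0 / min(p.k_leak, p.k_clear)
            t = np.linspace(0.0, tmax, 40001)
            numeric = np.trapezoid(bateman_transient(t, p), t)
            assert p.b_ler / p.k_clear == pytest.approx(numeric, rel=1e-5)

    def test_t_peak_random_parameters_vs_grid(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            p = BatemanParams(1.0, rng.uniform(5e-3, 40e-3), rng.uniform(5e-3, 40e-3))
            t = np.arange(0.0, 1200.0, 0.01)
            y = bateman_transient(t, p)
            assert abs(bateman_analytics(p).t_peak - t[np.argmax(y)]) <= 0.01


class TestPhaseDiagram:
    def k_leak_grid(self):
        return tuple(np.arange(8e-3, 35.1e-3, 3e-3))

    def test_grid_has_ten_points(self):
        assert len(self.k_leak_grid()) == 10

    def test_constant_store_amplification(self):
        spec = PhaseDiagramSpec(
            k_leak_grid=self.k_leak_grid(), b_ler_grid=(2.40,), k_clear=28e-3
        )
        transients, metrics = phase_diagram(spec)
        assert metrics.shape[0] == 10
        assert transients["k_leak"].nunique() == 10
        peaks = metrics["peak"].to_numpy()
        t_peaks = metrics["t_peak"].to_numpy()
        assert np.all(np.diff(peaks) > 0)  # progressive amplification
        assert np.all(np.diff(t_peaks) < 0)  # faster rise with stronger leak

    def test_declining_store_switches_to_attenuation(self):
        grid = self.k_leak_grid()
        b = declining_b_ler_schedule(len(grid), reference=2.40)
        assert b[0] == pytest.approx(2.40) and b[-1] == pytest.approx(0.36)
        spec = PhaseDiagramSpec(k_leak_grid=grid, b_ler_grid=b, k_clear=28e-3)
        _, metrics = phase_diagram(spec)
        peaks = metrics["peak"].to_numpy()
        i_max = int(np.argmax(peaks))
        assert 0 < i_max < len(peaks) - 1  # rises, then falls
        assert np.all(np.diff(peaks[: i_max + 1]) > 0)
        assert np.all(np.diff(peaks[i_max:]) < 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(DomainError):
            PhaseDiagramSpec(k_leak_grid=(), b_ler_grid=(1.0,), k_clear=28e-3)
        with pytest.raises(DomainError):
            PhaseDiagramSpec(k_leak_grid=(1e-3, 2e-3), b_ler_grid=(1.0, 2.0, 3.0), k_clear=28e-3)


@pytest.mark.parametrize("bad", [dict(b_ler=0.0), dict(k_leak=-1e-3), dict(k_clear=float("nan"))])
def test_invalid_bateman_params(bad):
    base = dict(b_ler=2.4, k_leak=14.55e-3, k_clear=28.34e-3)
    with pytest.raises(DomainError):
        BatemanParams(**{**base, **bad})
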
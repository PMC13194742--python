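"""Characterization metrics: modulus, conductivity, CSC, CIC, gel point,
current density, calcium activation."""

import numpy as np
import pytest

from hydrostim.metrics import (
    ElectrodeGeometry,
    calcium_activation_fraction,
    cic_from_pulse,
    csc_from_cv,
    current_density,
    four_point_conductivity,
    gel_point,
    young_modulus,
)
from hydrostim.synth import gen_biphasic_pulse, gen_cv, gen_rheology
from hydrostim.trace import TimeSeriesTrace


class TestYoungModulus:
    @pytest.mark.parametrize(
        "gs,gl,nu,expected",
        [
            (100.0, 50.0, 0.5, 335.41019662496847),
            (100.0, 0.0, 0.5, 300.0),  # elastic limit: E = 3 G'
            (0.0, 0.0, 0.3, 0.0),
        ],
    )
    def test_values(self, gs, gl, nu, expected):
        assert young_modulus(gs, gl, nu) == pytest.approx(expected, rel=1e-12)

    def test_incompressible_reduces_to_three_g_star(self):
        gs, gl = 123.0, 45.0
        assert young_modulus(gs, gl, 0.5) == pytest.approx(
            3.0 * np.hypot(gs, gl), rel=1e-12
        )

    def test_poisson_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            young_modulus(100.0, 10.0, 0.6)


class TestFourPointConductivity:
    BAR = ElectrodeGeometry(length=10e-3, width=2e-3, height=0.1e-3)

    def test_reference_bar(self):
        """10 x 2 x 0.1 mm bar, 1 mA at 1 V -> 50 S/m."""
        assert four_point_conductivity(1.0, 1e-3, self.BAR) == pytest.approx(50.0)

    def test_linear_in_current(self):
        s1 = four_point_conductivity(1.0, 1e-3, self.BAR)
        s2 = four_point_conductivity(1.0, 2e-3, self.BAR)
        assert s2 == pytest.approx(2 * s1)

    def test_linear_in_length(self):
        longer = ElectrodeGeometry(length=20e-3, width=2e-3, height=0.1e-3)
        assert four_point_conductivity(1.0, 1e-3, longer) == pytest.approx(
            2 * four_point_conductivity(1.0, 1e-3, self.BAR)
        )

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            four_point_conductivity(0.0, 1e-3, self.BAR)


class TestCsc:
    AREA = 0.0707  # cm^2, 3 mm disc electrode

    def test_ideal_capacitor_closed_form(self):
        """abs-mode CSC of an ideal capacitor is C*dE/A, scan-rate free."""
        for v in (0.02, 0.05, 0.2):
            cv = gen_cv(capacitance=1e-3, scan_rate=v, samples_per_cycle=2000)
            csc = csc_from_cv(cv, scan_rate=v, area_cm2=self.AREA)
            assert csc == pytest.approx(1e-3 * 1.0 / self.AREA * 1e3, rel=1e-3)

    def test_zero_current_zero_csc(self):
        e = np.concatenate([np.linspace(-0.5, 0.5, 50), np.linspace(0.5, -0.5, 50)])
        cv = TimeSeriesTrace(e, np.zeros_like(e), "potential", "current_a")
        assert csc_from_cv(cv, 0.05, self.AREA) == 0.0

    def test_signed_mode_cancels_on_symmetric_loop(self):
        cv = gen_cv(capacitance=1e-3)
        signed = csc_from_cv(cv, 0.05, self.AREA, rectify="as-printed")
        rectified = csc_from_cv(cv, 0.05, self.AREA, rectify="abs")
        assert abs(signed) < 1e-3 * rectified

    def test_open_trace_rejected(self):
        e = np.linspace(-0.5, 0.5, 100)
        cv = TimeSeriesTrace(e, np.ones_like(e), "potential", "current_a")
        with pytest.raises(ValueError, match="closed cycle"):
            csc_from_cv(cv, 0.05, self.AREA)


class TestCic:
    AREA = 0.0707

    def test_square_pulse_closed_form(self):
        """+/-100 uA, 60 us phases -> (6 nC + 6 nC)/0.0707 cm^2 ~ 0.17 uC/cm2."""
        pulse = gen_biphasic_pulse(amplitude=100e-6, phase_width=60e-6)
        cic = cic_from_pulse(pulse, area_cm2=self.AREA)
        assert cic == pytest.approx(2 * 100e-6 * 60e-6 / self.AREA * 1e6, rel=1e-3)
        assert cic == pytest.approx(0.17, rel=0.01)

    def test_homogeneous_in_amplitude(self):
        c1 = cic_from_pulse(gen_biphasic_pulse(amplitude=100e-6), self.AREA)
        c2 = cic_from_pulse(gen_biphasic_pulse(amplitude=200e-6), self.AREA)
        assert c2 == pytest.approx(2 * c1, rel=1e-9)

    def test_zero_trace_rejected_as_monophasic(self):
        t = np.linspace(0, 1e-3, 100)
        pulse = TimeSeriesTrace(t, np.zeros_like(t), "time", "current_a")
        with pytest.raises(ValueError, match="monophasic"):
            cic_from_pulse(pulse, self.AREA)

    def test_monophasic_trace_rejected(self):
        t = np.linspace(0, 1e-3, 100)
        pulse = TimeSeriesTrace(t, np.full_like(t, 1e-6), "time", "current_a")
        with pytest.raises(ValueError, match="monophasic"):
            cic_from_pulse(pulse, self.AREA)


class TestGelPoint:
    def test_recovers_analytic_crossover(self):
        from hydrostim.synth import rheology_crossover_time

        gs, gl = gen_rheology(dt=1.0)
        t_star = gel_point(gs, gl)
        truth = rheology_crossover_time(160.0, 20.0, 0.1, 60.0)
        assert t_star == pytest.approx(truth, abs=1.0)

    def test_already_gelled_returns_none(self):
        t = np.linspace(0, 10, 11)
        gs = TimeSeriesTrace(t, np.full_like(t, 100.0), "time", "g_storage_pa")
        gl = TimeSeriesTrace(t, np.full_like(t, 10.0), "time", "g_loss_pa")
        assert gel_point(gs, gl) is None

    def test_no_gelation_returns_none(self):
        t = np.linspace(0, 10, 11)
        gs = TimeSeriesTrace(t, np.full_like(t, 1.0), "time", "g_storage_pa")
        gl = TimeSeriesTrace(t, np.full_like(t, 10.0), "time", "g_loss_pa")
        assert gel_point(gs, gl) is None

    def test_mismatched_grids_rejected(self):
        gs = TimeSeriesTrace(np.linspace(0, 10, 11), np.ones(11), "time", "g")
        gl = TimeSeriesTrace(np.linspace(0, 10, 21), np.ones(21), "time", "g")
        with pytest.raises(ValueError, match="time grid"):
            gel_point(gs, gl)


class TestCurrentDensity:
    def test_inclusion_area_reference(self):
        """0.21 mA over the 0.0445 cm^2 projected inclusion area."""
        assert current_density(0.21e-3, 0.0445) == pytest.approx(4.72, rel=1e-3)

    def test_zero_current(self):
        assert current_density(0.0, 0.0445) == 0.0

    def test_area_ratio(self):
        j_small = current_density(0.21e-3, 0.0445)
        j_large = current_density(0.21e-3, 0.785)
        assert j_small / j_large == pytest.approx(0.785 / 0.0445, rel=1e-12)


class TestCalciumActivation:
    @staticmethod
    def _trace(peak):
        t = np.linspace(0, 50, 100)
        return TimeSeriesTrace(t, np.full_like(t, peak), "time", "df_over_f0")

    def test_counting(self):
        traces = [self._trace(2.0)] * 4 + [self._trace(0.1)] * 6
        assert calcium_activation_fraction(traces) == pytest.approx(0.4)

    def test_zero_threshold_activates_everything(self):
        traces = [self._trace(0.01)] * 5
        assert calcium_activation_fraction(traces, threshold=0.0) == 1.0

    def test_flat_traces_not_activated(self):
        traces = [self._trace(0.0)] * 5
        assert calcium_activation_fraction(traces) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calcium_activation_fraction([])
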
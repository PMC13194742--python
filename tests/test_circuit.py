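"""Layered capacitive-coupling circuit model and SAR evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrostim.circuit import (
    Layer,
    LayerStack,
    frequency_sweep,
    layer_impedance,
    load_stack,
    reference_stack,
    solve_stack,
    stack_from_config,
    sweep_table,
)
from hydrostim.dielectrics import EPS0, TissueMedium
from hydrostim.waveform import DriveSignal, make_drive


@pytest.fixture
def burst_drive():
    return make_drive(5e6, 2.5, 60e-6, 130.0)


class TestLayerImpedance:
    def test_brain_slab_reference_value(self, brain):
        """Resistive plus lossy-slab terms, checked term-by-term by hand."""
        z = layer_impedance(brain, 10e-3, 0.78e-5, 5e6, mode="as-printed")
        assert z.real == pytest.approx(7965.4, rel=1e-3)
        assert z.imag == pytest.approx(-2219.5, rel=1e-3)

    def test_parallel_rc_dc_limit_is_resistive(self, brain):
        z = layer_impedance(brain, 10e-3, 0.78e-5, 0.0, mode="parallel-rc")
        assert z == pytest.approx(10e-3 / (0.27 * 0.78e-5))
        assert z.imag == 0

    @pytest.mark.parametrize("mode", ["as-printed", "parallel-rc"])
    def test_doubling_area_halves_impedance(self, brain, mode):
        z1 = layer_impedance(brain, 1e-3, 1e-5, 1e6, mode=mode)
        z2 = layer_impedance(brain, 1e-3, 2e-5, 1e6, mode=mode)
        assert abs(z2) == pytest.approx(abs(z1) / 2, rel=1e-12)

    def test_insulator_is_purely_capacitive_as_printed(self):
        ins = TissueMedium("insulation", 0.0, 3.0)
        z = layer_impedance(ins, 5e-6, 0.78e-5, 5e6, mode="as-printed")
        assert z.real == 0
        expected = -1.0 / (2 * math.pi * 5e6 * EPS0 * 3.0 * 0.78e-5 / 5e-6)
        assert z.imag == pytest.approx(expected, rel=1e-12)

    def test_insulator_at_dc_is_singular(self):
        ins = TissueMedium("insulation", 0.0, 3.0)
        with pytest.raises(ZeroDivisionError):
            layer_impedance(ins, 5e-6, 0.78e-5, 0.0, mode="as-printed")

    def test_modes_agree_on_capacitive_term_when_displacement_dominates(self):
        """For omega*eps0*eps_r >> sigma the two modes differ only by the
        extra resistive term of the as-printed form."""
        m = TissueMedium("m", 1e-6, 1e4)
        d, a, f = 1e-3, 1e-5, 1e7
        z_printed = layer_impedance(m, d, a, f, mode="as-printed", sigma_floor=0)
        z_rc = layer_impedance(m, d, a, f, mode="parallel-rc")
        assert z_printed - d / (1e-6 * a) == pytest.approx(z_rc, rel=1e-6)


class TestSolveStack:
    def test_fixed_field_sar(self):
        """SAR = sigma*E^2/rho for the brain layer at a prescribed field."""
        sigma, e_field, rho = 0.27, 10.0, 1046.0
        assert sigma * e_field**2 / rho == pytest.approx(2.58e-2, rel=1e-3)

    def test_null_drive_gives_all_zeros(self, burst_drive):
        stack = reference_stack()
        drive = DriveSignal(5e6, 0.0, 60e-6, 130.0)
        sol = solve_stack(stack, drive)
        assert sol.current == 0
        assert sol.current_density == 0
        assert np.all(sol.layer_fields == 0)
        assert np.all(sol.layer_sar == 0)

    def test_series_additivity(self, burst_drive):
        sol = solve_stack(reference_stack(), burst_drive)
        assert sol.total_impedance == pytest.approx(
            sol.layer_impedances.sum(), rel=1e-12
        )

    @pytest.mark.parametrize("convention", ["burst", "continuous"])
    def test_reference_stack_sar_below_limit(self, burst_drive, convention):
        """The four-layer stack stays under the 2 W/kg exposure limit."""
        sol = solve_stack(reference_stack(), burst_drive, vrms_convention=convention)
        assert sol.brain_sar < 2.0

    @given(
        v=st.floats(0.1, 10.0),
        scale=st.floats(1.5, 4.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_sar_scales_with_vrms_squared(self, v, scale):
        stack = reference_stack()
        d1 = DriveSignal(5e6, v, 60e-6, 130.0)
        d2 = DriveSignal(5e6, v * scale, 60e-6, 130.0)
        s1 = solve_stack(stack, d1)
        s2 = solve_stack(stack, d2)
        assert s2.brain_sar == pytest.approx(s1.brain_sar * scale**2, rel=1e-9)


class TestFrequencySweep:
    def test_single_frequency_matches_solve_stack(self, burst_drive):
        stack = reference_stack()
        sols = frequency_sweep(stack, burst_drive, [5e6])
        direct = solve_stack(stack, burst_drive)
        assert sols[0].total_impedance == pytest.approx(direct.total_impedance)
        assert sols[0].brain_sar == pytest.approx(direct.brain_sar)

    @pytest.mark.parametrize("convention", ["burst", "continuous"])
    def test_sweep_max_sar_below_limit(self, burst_drive, convention):
        stack = reference_stack()
        freqs = np.logspace(5, np.log10(5e6), 40)
        sols = frequency_sweep(stack, burst_drive, freqs, vrms_convention=convention)
        assert max(s.brain_sar for s in sols) < 2.0

    def test_pure_capacitor_follows_one_over_omega(self):
        ins = TissueMedium("insulation", 0.0, 3.0)
        stack = LayerStack([Layer(ins, 5e-6)], area=0.78e-5)
        drive = DriveSignal(1e6, 2.5, mode="continuous")
        sols = frequency_sweep(stack, drive, [1e6, 2e6])
        assert abs(sols[0].total_impedance) == pytest.approx(
            2 * abs(sols[1].total_impedance), rel=1e-12
        )

    def test_sweep_table_columns(self, burst_drive):
        sols = frequency_sweep(reference_stack(), burst_drive, [1e6, 5e6])
        tab = sweep_table(sols)
        assert list(tab.columns) == [
            "frequency_hz",
            "z_abs_ohm",
            "current_a",
            "j_a_per_m2",
            "e_brain_v_per_m",
            "sar_brain_w_per_kg",
        ]
        assert len(tab) == 2

    def test_non_increasing_frequency_list_rejected(self, burst_drive):
        with pytest.raises(ValueError, match="increasing"):
            frequency_sweep(reference_stack(), burst_drive, [5e6, 1e6])


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tmp_path / "stack.yaml"
        cfg.write_text(
            "layers:\n"
            "  - {tissue: insulation, thickness_m: 5.0e-6}\n"
            "  - {tissue: scalp, thickness_m: 1.0e-3}\n"
            "  - {tissue: skull, thickness_m: 1.0e-3}\n"
            "  - {tissue: brain, thickness_m: 1.0e-2}\n"
            "area_m2: 0.78e-5\n"
            "brain_density_kg_m3: 1046\n"
            "mode: as-printed\n"
        )
        stack, mode = load_stack(cfg)
        assert mode == "as-printed"
        assert stack.layer_names == ["insulation", "scalp", "skull", "brain"]
        assert stack.area == pytest.approx(0.78e-5)

    def test_inline_properties_override_table(self):
        stack, _ = stack_from_config(
            {
                "layers": [
                    {
                        "tissue": "brain",
                        "thickness_m": 1e-2,
                        "conductivity_s_per_m": 0.5,
                        "relative_permittivity": 100,
                    }
                ],
                "area_m2": 1e-5,
            }
        )
        assert stack.layers[0].medium.conductivity == 0.5

    def test_invalid_mode_rejected_with_field_path(self):
        with pytest.raises(Exception, match="mode"):
            stack_from_config(
                {
                    "layers": [{"tissue": "brain", "thickness_m": 1e-2}],
                    "area_m2": 1e-5,
                    "mode": "bogus",
                }
            )
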
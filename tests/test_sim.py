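"""Forward-model correctness: closed forms against brute-force ODE oracles,
conservation laws, determinism, and monotonicity."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import bbbassay as bbb

TIMES = (10.0, 30.0, 60.0, 120.0)


def ode_receiver_oracle(config: bbb.SimulationConfig, with_cells: bool) -> np.ndarray:
    """Receiver concentrations by high-order numerical integration of
    dX_R/dt = PS·(C_L − C_R), independent of the closed-form engine."""
    fmt = config.format
    if with_cells:
        pe = (
            0.0
            if config.true_pe_endothelium == 0
            else 1.0 / (1.0 / config.true_pe_endothelium + 1.0 / config.true_pe_filter)
        )
    else:
        pe = config.true_pe_filter
    ps = pe * fmt.filter_area * 1000.0  # µL/min
    lam = config.nonspecific_loss_rate
    v_l, v_r = fmt.luminal_volume, fmt.abluminal_volume

    def rhs(t, x):
        flux = ps * (x[0] / v_l - x[1] / v_r)
        return [-flux - lam * x[0], flux]

    x0 = [config.initial_donor_concentration * v_l, 0.0]
    sol = solve_ivp(
        rhs, (0.0, config.sampling_times[-1]), x0,
        t_eval=config.sampling_times, rtol=1e-10, atol=1e-13, method="RK45",
    )
    return sol.y[1] / v_r


class TestTimecourse:
    @pytest.mark.parametrize("with_cells", [True, False])
    @pytest.mark.parametrize("loss", [0.0, 0.002])
    @pytest.mark.parametrize("format_name", ["12tw", "96tw_corning"])
    def test_closed_form_matches_ode_oracle(self, with_cells, loss, format_name):
        cfg = bbb.SimulationConfig(
            format=bbb.get_format(format_name),
            true_pe_endothelium=0.8e-3,
            true_pe_filter=7e-3,
            sampling_times=TIMES,
            nonspecific_loss_rate=loss,
        )
        tc = bbb.simulate_timecourse(cfg, with_cells=with_cells)
        expected = ode_receiver_oracle(cfg, with_cells)
        np.testing.assert_allclose(tc.receiver_conc, expected, rtol=1e-6)

    def test_zero_permeability_limit(self, corning):
        cfg = bbb.SimulationConfig(true_pe_endothelium=0.0, sampling_times=TIMES)
        tc = bbb.simulate_timecourse(cfg, with_cells=True)
        assert np.all(tc.receiver_conc == 0.0)
        np.testing.assert_allclose(tc.donor_conc, 1.0)

    def test_long_time_equilibrium(self, corning):
        cfg = bbb.SimulationConfig(sampling_times=(1e7,))
        tc = bbb.simulate_timecourse(cfg, with_cells=True)
        c_eq = 1.0 * corning.luminal_volume / (corning.luminal_volume + corning.abluminal_volume)
        assert tc.receiver_conc[-1] == pytest.approx(c_eq, rel=1e-9)
        assert tc.donor_conc[-1] == pytest.approx(c_eq, rel=1e-9)

    def test_mass_conservation(self, corning):
        cfg = bbb.SimulationConfig(sampling_times=TIMES, true_pe_endothelium=1e-3)
        tc = bbb.simulate_timecourse(cfg, with_cells=True)
        x0 = 1.0 * corning.luminal_volume
        total = (
            tc.donor_conc[1:] * corning.luminal_volume
            + tc.receiver_conc * corning.abluminal_volume
        )
        np.testing.assert_allclose(total, x0, rtol=1e-9)

    def test_nonspecific_loss_breaks_conservation_monotonically(self, corning):
        cfg = bbb.SimulationConfig(sampling_times=TIMES, nonspecific_loss_rate=0.001)
        tc = bbb.simulate_timecourse(cfg, with_cells=True)
        total = (
            tc.donor_conc[1:] * corning.luminal_volume
            + tc.receiver_conc * corning.abluminal_volume
        )
        assert np.all(np.diff(total) < 0) and total[0] < 70.0

    def test_same_seed_identical_different_seed_not(self):
        cfg = bbb.SimulationConfig(noise_cv=0.1, seed=5, sampling_times=TIMES)
        a = bbb.simulate_timecourse(cfg)
        b = bbb.simulate_timecourse(cfg)
        c = bbb.simulate_timecourse(replace(cfg, seed=6))
        np.testing.assert_array_equal(a.receiver_conc, b.receiver_conc)
        assert not np.array_equal(a.receiver_conc, c.receiver_conc)

    def test_receiver_monotone_in_true_pe(self):
        pes = [0.1e-3, 0.33e-3, 1e-3, 3e-3]
        curves = [
            bbb.simulate_timecourse(
                bbb.SimulationConfig(true_pe_endothelium=pe, sampling_times=TIMES)
            ).receiver_conc
            for pe in pes
        ]
        for low, high in zip(curves, curves[1:]):
            assert np.all(high > low)

    def test_filter_must_be_leakier_than_endothelium(self):
        with pytest.raises(bbb.ValidationError):
            bbb.SimulationConfig(true_pe_endothelium=5e-3, true_pe_filter=1e-3)

    def test_sampling_times_must_increase(self):
        with pytest.raises(bbb.ValidationError):
            bbb.SimulationConfig(sampling_times=(30.0, 10.0))


class TestEffluxSim:
    def test_matches_ode_oracle(self):
        cfg = bbb.EffluxSimConfig(
            uptake_rate=0.03, passive_efflux_rate=0.012, active_efflux_rate=0.02,
            inhibition_fraction=0.4, duration=90.0,
        )
        k_out = 0.012 + 0.02 * 0.6
        sol = solve_ivp(
            lambda t, x: [0.03 * 5.0 - k_out * x[0]],
            (0.0, 90.0), [0.0], t_eval=[90.0], rtol=1e-10, atol=1e-13,
        )
        got = bbb.simulate_efflux_assay(cfg)[0]
        assert got == pytest.approx(sol.y[0][-1], rel=1e-6)

    def test_no_active_efflux_inhibitor_is_inert(self):
        base = dict(active_efflux_rate=0.0, seed=3)
        a = bbb.simulate_efflux_assay(bbb.EffluxSimConfig(inhibition_fraction=0.0, **base))
        b = bbb.simulate_efflux_assay(bbb.EffluxSimConfig(inhibition_fraction=1.0, **base))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("active", [0.004, 0.008, 0.05])
    def test_inhibition_strictly_raises_signal(self, active):
        lo = bbb.simulate_efflux_assay(
            bbb.EffluxSimConfig(active_efflux_rate=active, inhibition_fraction=0.0)
        )
        hi = bbb.simulate_efflux_assay(
            bbb.EffluxSimConfig(active_efflux_rate=active, inhibition_fraction=1.0)
        )
        assert hi[0] > lo[0]

    def test_invalid_inhibition_fraction(self):
        with pytest.raises(bbb.ValidationError):
            bbb.EffluxSimConfig(inhibition_fraction=1.5)


class TestDisruptionModel:
    def test_hill_closed_forms(self):
        m = bbb.DisruptionModel(baseline_pe=0.33e-3, max_pe=5e-3, ec50=2.0, hill_coefficient=1.7)
        assert m.pe_at(0.0) == 0.33e-3
        midpoint = 0.33e-3 + 0.5 * (5e-3 - 0.33e-3)
        assert m.pe_at(2.0) == pytest.approx(midpoint, rel=1e-12)
        m1 = bbb.DisruptionModel(hill_coefficient=1.0, ec50=1.0)
        ninety = m1.baseline_pe + 0.9 * (m1.max_pe - m1.baseline_pe)
        assert m1.pe_at(9.0) == pytest.approx(ninety, rel=1e-12)

    def test_invalid_models_rejected(self):
        with pytest.raises(bbb.ValidationError):
            bbb.DisruptionModel(baseline_pe=2e-3, max_pe=1e-3)
        with pytest.raises(bbb.ValidationError):
            bbb.DisruptionModel(ec50=-1.0)

    def test_dose_response_series_shape(self):
        conc = bbb.dilution_series(0.1, 10)
        series = bbb.simulate_dose_response(
            bbb.DisruptionModel(), conc, n_replicates=2,
            assay=bbb.SimulationConfig(noise_cv=0.02, seed=1),
        )
        assert series.concentrations == tuple(conc)
        assert all(r.size == 2 for r in series.pe_replicates)
        assert series.control_pe.size == 2


class TestIvivcDataset:
    def test_round_trip_single_compound(self):
        df = bbb.simulate_ivivc_dataset([0.5], [80.0])
        rec = bbb.compute_records(df)[0]
        assert rec.recovery_pct == pytest.approx(80.0, rel=1e-12)
        assert rec.kpuu_invitro == pytest.approx(0.5, rel=1e-12)

    def test_full_recovery_round_trip(self):
        df = bbb.simulate_ivivc_dataset([1.0], [100.0])
        rec = bbb.compute_records(df)[0]
        assert rec.kpuu_invitro == pytest.approx(1.0, rel=1e-12)

    def test_nine_compound_log_spaced_round_trip(self):
        kpuu = np.geomspace(0.01, 1.5, 9)
        df = bbb.simulate_ivivc_dataset(kpuu, [100.0] * 9)
        got = np.array([r.kpuu_invitro for r in bbb.compute_records(df)])
        np.testing.assert_allclose(got, kpuu, rtol=1e-9)

    def test_infeasible_combination_rejected(self):
        with pytest.raises(bbb.ValidationError, match="infeasible"):
            bbb.simulate_ivivc_dataset([0.05], [80.0])

    def test_noise_is_seeded(self):
        a = bbb.simulate_ivivc_dataset([0.5, 1.0], [90.0, 95.0], noise_cv=0.1, seed=4)
        b = bbb.simulate_ivivc_dataset([0.5, 1.0], [90.0, 95.0], noise_cv=0.1, seed=4)
        c = bbb.simulate_ivivc_dataset([0.5, 1.0], [90.0, 95.0], noise_cv=0.1, seed=5)
        assert a.equals(b) and not a.equals(c)
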
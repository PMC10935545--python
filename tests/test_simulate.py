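"""Unit tests for the trench simulator update rules and engine."""

import math

import numpy as np
import pandas as pd
import pytest

import trenchox as tx
from trenchox.simulate import (CellState, _growth_factor, h2o2_profile,
                               step_fate_and_mismatch, surface_area)


def make_cell(**kw):
    defaults = dict(length=2.6, enzyme_level=0.9, genotype="WT", alive=True)
    defaults.update(kw)
    return CellState(**defaults)


class TestH2O2Profile:
    def test_empty_trench_gives_empty_profile(self):
        cfg = tx.SimConfig()
        assert h2o2_profile([], 100.0, cfg) == []

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            h2o2_profile([make_cell()], -1.0, tx.SimConfig())

    def test_single_barrier_at_reported_attenuation(self):
        # a wild-type barrier at steady state removes 32.3%
        cfg = tx.SimConfig(attenuation_mode="fixed", fixed_attenuation=0.323)
        prof = h2o2_profile([make_cell(), make_cell()], 100.0, cfg)
        assert prof[0] == pytest.approx(100.0)
        assert prof[1] == pytest.approx(67.7)

    def test_six_barriers_product(self):
        # product oracle evaluated term by term: c behind six identical cells
        cfg = tx.SimConfig(attenuation_mode="fixed", fixed_attenuation=0.323)
        cells = [make_cell() for _ in range(6)] + [make_cell()]
        prof = h2o2_profile(cells, 100.0, cfg)
        expected = 100.0
        for _ in range(6):
            expected *= 1.0 - 0.323
        assert prof[-1] == pytest.approx(expected)
        assert prof[-1] == pytest.approx(9.63, abs=5e-3)

    def test_inert_and_dead_cells_do_not_shield(self):
        cfg = tx.SimConfig()
        inert = make_cell(genotype="inert")
        dead = make_cell(alive=False)
        focal = make_cell()
        prof = h2o2_profile([inert, dead, focal], 50.0, cfg)
        assert prof == [50.0, 50.0, 50.0]

    def test_profile_monotone_and_log_linear(self):
        cfg = tx.SimConfig(attenuation_mode="fixed", fixed_attenuation=0.25)
        cells = [make_cell() for _ in range(8)]
        prof = np.array(h2o2_profile(cells, 80.0, cfg))
        assert (np.diff(prof) <= 0).all()
        slopes = np.diff(np.log(prof))
        assert np.allclose(slopes, math.log(0.75))


class TestStepGrowth:
    def test_no_stress_pure_exponential(self):
        cfg = tx.SimConfig()
        cell = make_cell(length=2.0, elongation_rate=0.03, internal_h2o2=0.0)
        for _ in range(180):  # 45 min at 0.25 min steps
            tx.step_growth(cell, 0.0, 0.25, cfg)
        assert cell.length == pytest.approx(2.0 * math.exp(0.03 * 45.0), rel=1e-9)

    def test_hill_midpoint_halves_growth(self):
        cfg = tx.SimConfig()
        g = float(_growth_factor(cfg.growth_inhibition.k_uM, cfg))
        assert g == pytest.approx(0.5)

    def test_trajectory_matches_closed_form_at_fixed_inhibition(self):
        # hold the internal concentration fixed: L(t) = L0 exp(beta*g*t)
        cfg = tx.SimConfig()
        cfg.internal_relaxation_rate = 1e9  # pin c_int to its target instantly
        cell = make_cell(length=1.9, elongation_rate=0.028, enzyme_level=0.5)
        c_local = 30.0
        c_int = c_local / (1.0 + cfg.internal_scavenging_strength * 0.5)
        g = float(_growth_factor(c_int, cfg))
        for _ in range(180):
            tx.step_growth(cell, c_local, 0.25, cfg)
        assert cell.length == pytest.approx(1.9 * math.exp(0.028 * g * 45.0), rel=1e-6)

    def test_dead_and_inert_cells_do_not_elongate(self):
        cfg = tx.SimConfig()
        for cell in (make_cell(alive=False), make_cell(genotype="inert")):
            L0 = cell.length
            tx.step_growth(cell, 0.0, 1.0, cfg)
            assert cell.length == L0


class TestStepResponse:
    def test_delta_oxyr_never_induces(self):
        cfg = tx.SimConfig()
        cell = make_cell(genotype="delta_oxyR",
                         enzyme_level=cfg.enzyme.basal_level,
                         internal_h2o2=80.0)
        for _ in range(400):
            tx.step_response(cell, 80.0, 0.25, cfg)
        assert cell.enzyme_level == pytest.approx(cfg.enzyme.basal_level)

    def test_reporter_settles_at_basal_over_dilution(self):
        # without stress the intensity fixed point is basal rate / growth rate
        cfg = tx.SimConfig()
        beta = cfg.base_elongation_rate
        cell = make_cell(length=2.0, elongation_rate=beta,
                         enzyme_level=cfg.enzyme.basal_level)
        cell.reporter = 0.0
        for _ in range(4 * 600):  # 10 h
            tx.step_growth(cell, 0.0, 0.25, cfg)
            tx.step_response(cell, 0.0, 0.25, cfg)
            if cell.length >= 4.0:  # renormalise instead of dividing
                cell.length /= 2.0
                cell.reporter /= 2.0
        intensity = cell.reporter / cell.area(cfg)
        assert intensity == pytest.approx(cfg.reporter.basal_rate / beta, rel=0.02)

    def test_reporter_production_rises_after_configured_delay(self):
        cfg = tx.SimConfig()
        cfg.enzyme.delay_min = 2.0
        cfg.reporter.delay_min = 12.0
        cell = make_cell(enzyme_level=cfg.enzyme.basal_level, internal_h2o2=50.0)
        dt = 0.25
        rates = []
        for k in range(80):  # 20 min
            before = cell.reporter
            tx.step_response(cell, 50.0, dt, cfg)
            rates.append((cell.reporter - before) / dt)
        rates = np.array(rates)
        base = rates[0]
        onset_step = int(np.argmax(rates > 2.0 * base))
        assert abs(onset_step * dt - cfg.reporter.delay_min) <= dt + 1e-9


class TestDivideAndPush:
    def test_below_threshold_unchanged(self):
        cfg = tx.SimConfig()
        rng = np.random.default_rng(0)
        trench = [make_cell(length=2.0, division_length=4.0)]
        out = tx.divide_and_push(trench, cfg, rng)
        assert len(out) == 1 and out[0] is trench[0]

    def test_division_conserves_reporter_content(self):
        cfg = tx.SimConfig(partition_noise_sd=0.0)
        rng = np.random.default_rng(1)
        parent = make_cell(length=4.0, division_length=3.9, reporter=1000.0,
                           marker=500.0, internal_h2o2=0.0)
        out = tx.divide_and_push([parent], cfg, rng)
        assert len(out) == 2
        assert out[0].reporter + out[1].reporter == pytest.approx(1000.0)
        assert out[0].marker + out[1].marker == pytest.approx(500.0)
        assert out[0].length == out[1].length == pytest.approx(2.0)
        assert {c.parent_id for c in out} == {parent.cell_id}

    def test_noisy_division_still_conserves_content(self):
        cfg = tx.SimConfig(partition_noise_sd=0.1)
        rng = np.random.default_rng(2)
        parent = make_cell(length=4.2, division_length=4.0, reporter=730.0)
        out = tx.divide_and_push([parent], cfg, rng)
        assert out[0].reporter + out[1].reporter == pytest.approx(730.0)

    def test_long_run_order_and_exit_audit(self):
        # grow a trench for many steps; order must be preserved, positions
        # must stack contiguously and exits must only occur at the open end
        cfg = tx.SimConfig()
        rng = np.random.default_rng(3)
        trench = [make_cell(cell_id=i + 1, length=2.0 + 0.1 * i,
                            internal_h2o2=0.0) for i in range(6)]
        counter = [100]
        seen = {c.cell_id for c in trench}
        for _ in range(600):
            for cell in trench:
                tx.step_growth(cell, 0.0, 0.25, cfg)
            before = [c.cell_id for c in trench]
            trench = tx.divide_and_push(trench, cfg, rng, id_counter=counter)
            after = [c.cell_id for c in trench]
            # order audit: ids surviving the step keep their relative order
            survivors = [i for i in after if i in set(before)]
            assert survivors == [i for i in before if i in set(after)]
            # position audit: contiguous stacking from the closed end
            pos = 0.0
            for cell in trench:
                assert cell.position == pytest.approx(pos)
                pos += cell.length
            assert pos <= cfg.trench_length_um + 1e-9
            # exits only from the open end: the mother lineage never vanishes
            assert len(trench) >= 1
            seen.update(after)


class TestFateAndMismatch:
    def test_zero_rates_emit_no_foci(self):
        cfg = tx.SimConfig()
        cfg.mismatch.basal = 0.0
        cfg.mismatch.induced_per_uM = 0.0
        rng = np.random.default_rng(0)
        cell = make_cell(internal_h2o2=50.0, enzyme_level=0.2)
        total = sum(step_fate_and_mismatch(cell, 1.0, cfg, rng)[1]
                    for _ in range(100))
        assert total == 0

    def test_poisson_mean_matches_rate(self):
        cfg = tx.SimConfig()
        cfg.mismatch.basal = 0.0
        cfg.mismatch.induced_per_uM = 1e-3
        cfg.death.lethal_uM = 1e9
        rng = np.random.default_rng(4)
        c_int, E, dt = 40.0, 0.5, 1.0
        lam = 1e-3 * c_int * (1.0 - E)
        n_cells, n_steps = 200, 100  # 2e4 cell-frames
        total = 0
        for _ in range(n_cells):
            cell = make_cell(internal_h2o2=c_int, enzyme_level=E)
            for _ in range(n_steps):
                _, foci = step_fate_and_mismatch(cell, dt, cfg, rng)
                total += foci
        expect = lam * dt * n_cells * n_steps
        assert abs(total - expect) <= 3.0 * math.sqrt(expect)

    def test_primed_cell_survives_where_naive_dies(self):
        cfg = tx.SimConfig()
        d = cfg.death
        c = d.lethal_uM + 0.5 * d.priming_coefficient_uM  # kills naive only
        rng = np.random.default_rng(5)
        naive = make_cell(enzyme_level=0.0, internal_h2o2=c)
        primed = make_cell(enzyme_level=0.9, internal_h2o2=c)
        for _ in range(int(d.sustained_min / 0.25) + 1):
            step_fate_and_mismatch(naive, 0.25, cfg, rng)
            step_fate_and_mismatch(primed, 0.25, cfg, rng)
        assert not naive.alive
        assert primed.alive

    def test_death_clock_resets_below_tolerance(self):
        cfg = tx.SimConfig()
        rng = np.random.default_rng(6)
        cell = make_cell(enzyme_level=0.0,
                         internal_h2o2=cfg.death.lethal_uM + 5.0)
        step_fate_and_mismatch(cell, cfg.death.sustained_min - 1.0, cfg, rng)
        cell.internal_h2o2 = 0.0
        step_fate_and_mismatch(cell, 1.0, cfg, rng)
        cell.internal_h2o2 = cfg.death.lethal_uM + 5.0
        step_fate_and_mismatch(cell, cfg.death.sustained_min - 1.0, cfg, rng)
        assert cell.alive


class TestSimulate:
    def test_identical_seeds_identical_tables(self):
        cfg = tx.SimConfig(n_trenches=3, t_start_min=-15.0, t_end_min=30.0, seed=9)
        a, ma = tx.simulate(cfg, tx.TreatmentSchedule.step(100.0))
        b, mb = tx.simulate(cfg, tx.TreatmentSchedule.step(100.0))
        pd.testing.assert_frame_equal(a, b)
        assert ma == mb

    def test_trench_streams_independent_of_count(self):
        cfg3 = tx.SimConfig(n_trenches=3, t_start_min=0.0, t_end_min=30.0, seed=9)
        cfg5 = cfg3.replace(n_trenches=5)
        a, _ = tx.simulate(cfg3, tx.TreatmentSchedule([]))
        b, _ = tx.simulate(cfg5, tx.TreatmentSchedule([]))
        pd.testing.assert_frame_equal(a, b[b.trench_id < 3].reset_index(drop=True))

    def test_untreated_run_stays_basal(self):
        cfg = tx.SimConfig(n_trenches=10, t_start_min=0.0, t_end_min=180.0, seed=7)
        df, meta = tx.simulate(cfg, tx.TreatmentSchedule([]))
        basal = cfg.reporter.basal_rate / cfg.base_elongation_rate
        late = df[df.time_min > 120.0]
        assert abs(late.reporter_au.mean() - basal) < 0.15 * basal
        assert meta["died"] == 0
        counts = late.groupby(["trench_id", "frame"]).size()
        assert 6.0 <= counts.mean() <= 11.0

    def test_surface_area_reduces_to_cylinder_formula(self):
        # hemisphere-capped cylinder: total envelope area is exactly 2*pi*r*L
        assert surface_area(2.6, 1.2) == pytest.approx(2 * math.pi * 0.6 * 2.6)

    def test_genotype_mix_proportions(self):
        cfg = tx.SimConfig(n_trenches=40, t_start_min=0.0, t_end_min=3.0, seed=3,
                           genotype_mix={"WT": 0.7, "delta_oxyR": 0.3})
        df, _ = tx.simulate(cfg, tx.TreatmentSchedule([]))
        frac = (df[df.frame == 0].genotype == "delta_oxyR").mean()
        assert 0.15 <= frac <= 0.45


def test_damkohler_number_with_reported_constants():
    # catalase turnover over envelope permeation for a 1.2 um cell
    assert tx.damkohler_number(5.4e4, 1.2e-6, 1.6e-5) == pytest.approx(4050.0)
    with pytest.raises(ValueError):
        tx.damkohler_number(length_m=0.0)
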
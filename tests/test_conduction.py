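"""Block limits, neighbor pairing, plane-fit CV, circular statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

import fibwave as fw
from fibwave import conduction
from fibwave import synthetic_af as sa


class TestBlockLimits:
    @pytest.mark.parametrize(
        "spacing,v,relation,expected",
        [
            (2.5, 20.0, "orthogonal", 12),
            (2.5, 20.0, "oblique", 17),
            (2.5, 250.0, "orthogonal", 1),
        ],
    )
    def test_printed_limits(self, spacing, v, relation, expected):
        assert conduction.max_at_difference(spacing, v, relation) == expected

    def test_monotone_in_velocity_and_spacing(self):
        for v1, v2 in [(10, 20), (20, 40), (40, 80)]:
            assert conduction.max_at_difference(2.5, v1) >= conduction.max_at_difference(2.5, v2)
        for s1, s2 in [(1.0, 2.5), (2.5, 5.0)]:
            assert conduction.max_at_difference(s1, 20) <= conduction.max_at_difference(s2, 20)


class TestLinkPairing:
    def test_planar_wave_all_links_paired_and_conducted(self, grid12, planar_series):
        series, _ = planar_series
        links = conduction.classify_links(
            conduction.pair_neighbor_activations(series, grid12),
            conduction.block_limits(grid12),
        )
        assert all(l.status == "conducted" for l in links)
        assert conduction.dissociation_index(links) == 0.0

    def test_silent_neighbor_unpaired(self, grid12):
        s = fw.ActivationSeries({0: [10.0]}, 0.0, 100.0)
        links = conduction.pair_neighbor_activations(s, grid12, 50.0)
        assert {l.status for l in links} == {"unpaired"}

    def test_pairing_symmetric_in_absolute_delay(self, grid12):
        rng = np.random.default_rng(0)
        times = {e: np.sort(rng.uniform(0, 500, 3)) for e in range(grid12.n_active)}
        times = {
            e: t for e, t in times.items() if np.all(np.diff(t) >= 40)
        }
        s = fw.ActivationSeries(times, 0.0, 500.0)
        links = conduction.pair_neighbor_activations(s, grid12, 80.0)
        seen = {}
        for l in links:
            if l.delta_t_ms is None:
                continue
            key = (min(l.electrode_a, l.electrode_b), max(l.electrode_a, l.electrode_b),
                   round(min(l.t_a_ms, l.t_b_ms), 6))
            seen.setdefault(key, set()).add(round(abs(l.delta_t_ms), 9))
        assert all(len(v) == 1 for v in seen.values())

    def test_classification_boundary_cases(self):
        limits = {"orthogonal": 12, "oblique": 17}
        mk = lambda rel, dt: conduction.NeighborLinkSample(0, 1, rel, 0.0, dt, dt)
        out = conduction.classify_links(
            [mk("orthogonal", 12.0), mk("orthogonal", 13.0),
             mk("oblique", 17.0), mk("oblique", 18.0), mk("orthogonal", 0.0)],
            limits,
        )
        assert [l.status for l in out] == [
            "conducted", "blocked", "conducted", "blocked", "conducted"
        ]


class TestPlaneFitCv:
    def test_planar_wave_speed_and_direction(self, grid12, planar_series):
        series, _ = planar_series
        for e in [e for e in range(grid12.n_active) if not grid12.is_peripheral(e)][:30]:
            est = fw.fit_local_cv(series, grid12, (e, series.times[e][0]))
            assert est.valid
            assert est.speed_cm_s == pytest.approx(100.0, rel=0.01)
            assert abs(est.direction_rad) < 0.02

    def test_diagonal_wave_direction(self, grid12):
        xy = grid12.coordinates
        at = 1.0 + (xy[:, 0] + xy[:, 1]) / math.sqrt(2.0)  # 100 cm/s at 45 deg
        s = fw.ActivationSeries({e: [at[e]] for e in range(grid12.n_active)}, 0.0, 60.0)
        e = [e for e in range(grid12.n_active) if not grid12.is_peripheral(e)][0]
        est = fw.fit_local_cv(s, grid12, (e, s.times[e][0]))
        assert est.speed_cm_s == pytest.approx(100.0, rel=0.01)
        assert est.direction_rad == pytest.approx(math.pi / 4, abs=0.02)

    def test_simultaneous_neighbors_invalid(self, grid12):
        s = fw.ActivationSeries(
            {e: [10.0] for e in range(grid12.n_active)}, 0.0, 100.0
        )
        e = 40
        est = fw.fit_local_cv(s, grid12, (e, 10.0))
        assert not est.valid

    def test_too_few_neighbors_invalid(self, grid12):
        s = fw.ActivationSeries({40: [10.0], 41: [12.0]}, 0.0, 100.0)
        est = fw.fit_local_cv(s, grid12, (40, 10.0))
        assert not est.valid
        assert est.n_neighbors_used < 3

    def test_speed_invariant_under_grid_rotation(self, grid12):
        # a plane wave at an arbitrary angle recovers the same speed
        theta = 0.7
        v = 80.0 / 100.0  # mm/ms
        xy = grid12.coordinates
        at = 1.0 + (xy[:, 0] * math.cos(theta) + xy[:, 1] * math.sin(theta)) / v
        s = fw.ActivationSeries({e: [at[e]] for e in range(grid12.n_active)}, 0.0, 80.0)
        interior = [e for e in range(grid12.n_active) if not grid12.is_peripheral(e)]
        speeds = [fw.fit_local_cv(s, grid12, (e, s.times[e][0])).speed_cm_s
                  for e in interior]
        assert np.median(speeds) == pytest.approx(80.0, rel=0.01)


class TestCircularStats:
    def test_constant_directions_index_one(self):
        ests = [conduction.CvEstimate(0, i * 10.0, 50.0, 0.3, 5, 0.0, True)
                for i in range(5)]
        assert conduction.anisotropy_index(ests)[0] == pytest.approx(1.0)

    def test_symmetric_directions_index_zero(self):
        dirs = [0.0, math.pi / 2, math.pi, 3 * math.pi / 2]
        ests = [conduction.CvEstimate(0, i * 50.0, 50.0, d, 5, 0.0, True)
                for i, d in enumerate(dirs)]
        assert conduction.anisotropy_index(ests)[0] == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_matches_analytic_resultant_length(self):
        kappa = 4.0
        rng = np.random.default_rng(123)
        dirs = rng.vonmises(0.5, kappa, size=200)
        expected = special.i1(kappa) / special.i0(kappa)
        assert conduction.mean_resultant_length(dirs) == pytest.approx(expected, abs=0.05)

    def test_agrees_with_scipy_circvar(self):
        rng = np.random.default_rng(5)
        dirs = rng.uniform(-math.pi, math.pi, 50)
        r = conduction.mean_resultant_length(dirs)
        assert 1.0 - r == pytest.approx(stats.circvar(dirs), abs=1e-12)

    def test_fewer_than_three_estimates_excluded(self):
        ests = [conduction.CvEstimate(0, 0.0, 50.0, 0.1, 5, 0.0, True),
                conduction.CvEstimate(0, 50.0, 50.0, 0.2, 5, 0.0, True)]
        assert conduction.anisotropy_index(ests) == {}

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-math.pi, math.pi), min_size=1, max_size=30),
           st.floats(-math.pi, math.pi))
    def test_bounded_and_rotation_invariant(self, dirs, shift):
        r = conduction.mean_resultant_length(dirs)
        assert -1e-12 <= r <= 1.0 + 1e-12
        r2 = conduction.mean_resultant_length(np.asarray(dirs) + shift)
        assert r2 == pytest.approx(r, abs=1e-9)


class TestAfclAndWavelength:
    def test_periodic_series_exact(self):
        times = {e: 10.0 + 150.0 * np.arange(5) for e in range(4)}
        s = fw.ActivationSeries(times, 0.0, 1000.0)
        per_e, regional = fw.afcl(s)
        assert regional == 150.0
        assert all(v == 150.0 for v in per_e.values())

    def test_median_of_intervals(self):
        s = fw.ActivationSeries({0: [0.0, 140.0, 290.0, 450.0]}, 0.0, 500.0)
        per_e, _ = fw.afcl(s)
        assert per_e[0] == 150.0  # intervals 140, 150, 160

    def test_jittered_episode_recovers_mean_cycle_length(self, mapping_grid):
        series, _ = sa.simulate_af_episode(
            mapping_grid, mean_afcl_ms=185.0, jitter_sd_ms=5.0,
            focal_rate_per_s=0.0, n_block_lines=0, duration_ms=4000.0, seed=2,
        )
        _, regional = fw.afcl(series)
        assert regional == pytest.approx(185.0, abs=3.0)

    def test_undefined_without_enough_activations(self):
        s = fw.ActivationSeries({0: [10.0, 60.0]}, 0.0, 100.0)
        with pytest.raises(ValueError):
            fw.afcl(s)

    @pytest.mark.parametrize("erp,cv,wl", [(200, 50, 100), (0.001, 100, 0.001),
                                           (250, 80, 200)])
    def test_wavelength_arithmetic(self, erp, cv, wl):
        assert fw.wavelength(erp, cv) == pytest.approx(wl)
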
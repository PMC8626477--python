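"""Contour-sweep enclosure statistics and map-model correlation."""

import numpy as np
import pytest

from conftest import make_model
from corescaffold.density import DensityMap
from corescaffold.enclosure import (ContourSweep, EnclosureProfile,
                                    confidence_band, contour_sweep_profile,
                                    count_uncovered_atoms,
                                    enclosure_probability, map_model_cc,
                                    map_values_at)
from corescaffold.synth import (MapSimulationConfig, build_toy_assembly,
                                element_selections, simulate_map)


def flat_map(value, n=8, voxel=1.0):
    return DensityMap(grid=np.full((n, n, n), float(value)),
                      voxel_size=[voxel] * 3, origin=[0, 0, 0])


class TestInterpolation:
    def test_grid_node_value(self):
        g = np.zeros((4, 4, 4))
        g[2, 1, 3] = 7.5  # z, y, x
        dmap = DensityMap(grid=g, voxel_size=[1, 1, 1], origin=[0, 0, 0])
        v, inside = map_values_at(dmap, np.array([[3.0, 1.0, 2.0]]))
        assert inside[0] and v[0] == pytest.approx(7.5)

    def test_midpoint_linear(self):
        g = np.zeros((4, 4, 4))
        g[0, 0, 1] = 1.0
        dmap = DensityMap(grid=g, voxel_size=[1, 1, 1], origin=[0, 0, 0])
        v, _ = map_values_at(dmap, np.array([[0.5, 0.0, 0.0]]))
        assert v[0] == pytest.approx(0.5)

    def test_constant_map_everywhere(self):
        dmap = flat_map(2.5)
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 7, size=(1000, 3))
        v, inside = map_values_at(dmap, pts)
        assert inside.all()
        np.testing.assert_allclose(v, 2.5)

    def test_outside_positions_flagged(self):
        dmap = flat_map(1.0)
        v, inside = map_values_at(dmap, np.array([[100.0, 0, 0]]))
        assert not inside[0] and v[0] == -np.inf


class TestUncoveredCounts:
    def test_threshold_semantics(self):
        dmap = flat_map(0.03)
        atoms = make_model([("A", i, "GLY", "CA", "C", (2.0 + i * 0.1, 2, 2))
                            for i in range(5)])
        assert count_uncovered_atoms(dmap, atoms, 0.02) == 0
        assert count_uncovered_atoms(dmap, atoms, 0.04) == 5
        # equality counts as covered
        assert count_uncovered_atoms(dmap, atoms, 0.03) == 0

    def test_empty_selection_is_error(self):
        from corescaffold.model import AtomModel
        with pytest.raises(ValueError):
            count_uncovered_atoms(flat_map(1), AtomModel.empty(), 0.5)

    def test_planted_weights_control_coverage(self, planted_scenario,
                                              planted_map):
        model, dmap = planted_map
        sels = element_selections(planted_scenario)
        chains = planted_scenario.core_chain_ids
        level = 0.03  # mid-sweep, far below the weighted element's density
        from corescaffold.model import select_atoms
        covered = count_uncovered_atoms(dmap, select_atoms(model, sels[chains[0]]),
                                        level)
        absent = count_uncovered_atoms(dmap, select_atoms(model, sels[chains[-1]]),
                                       level)
        assert covered == 0
        assert absent == planted_scenario.element_atom_count


class TestSweep:
    def test_level_counts(self):
        assert ContourSweep(0.015, 0.052, 0.0005).n_levels == 75
        assert ContourSweep(0, 1, 0.5).n_levels == 3

    def test_constant_map_profile(self):
        dmap = flat_map(0.03, n=16)
        atoms = {c: make_model([("A", i, "GLY", "CA", "C",
                                 (5.0 + i, 5 + k, 5)) for i in range(3)])
                 for k, c in enumerate("AB")}
        sweep = ContourSweep(0.015, 0.052, 0.0005)
        prof = contour_sweep_profile(dmap, atoms, sweep)
        for row in prof.counts:
            np.testing.assert_array_equal(row[prof.levels <= 0.03], 0)
            np.testing.assert_array_equal(row[prof.levels > 0.03], 3)

    def test_counts_monotone_in_level(self, planted_scenario, planted_map):
        model, dmap = planted_map
        prof = contour_sweep_profile(dmap, element_selections(planted_scenario),
                                     ContourSweep(), model=model)
        assert np.all(np.diff(prof.counts, axis=1) >= 0)

    def test_unequal_atom_counts_rejected(self):
        dmap = flat_map(1.0)
        atoms = {"A": make_model([("A", 1, "G", "CA", "C", (2, 2, 2))]),
                 "B": make_model([("B", 1, "G", "CA", "C", (3, 3, 3)),
                                  ("B", 2, "G", "CA", "C", (4, 4, 4))])}
        with pytest.raises(ValueError, match="unequal"):
            contour_sweep_profile(dmap, atoms, ContourSweep(0, 1, 0.5))


class TestBandAndProbability:
    def make_profile(self, counts):
        counts = np.asarray(counts)
        return EnclosureProfile(
            subunit_ids=[f"s{i}" for i in range(counts.shape[0])],
            levels=np.arange(counts.shape[1], dtype=float),
            counts=counts, atoms_per_subunit=int(counts.max(initial=1)))

    def test_identical_subunits_collapse_band(self):
        prof = self.make_profile(np.tile([0, 1, 2, 3], (5, 1)))
        band = confidence_band(prof)
        np.testing.assert_array_equal(band.sigma, 0)
        np.testing.assert_array_equal(band.ci_lower, band.mu)
        np.testing.assert_array_equal(band.ci_upper, band.mu)

    def test_halfwidth_is_z_sigma_over_sqrt_m(self):
        # with M = 60 subunits, a level whose sample sd is √60 must get a
        # half-width of exactly z = 3.291; checked via the general identity
        rng = np.random.default_rng(0)
        counts = np.sort(rng.integers(0, 30, size=(60, 5)), axis=1)
        prof = self.make_profile(counts)
        band = confidence_band(prof)
        np.testing.assert_allclose(band.ci_upper - band.mu,
                                   3.291 * band.sigma / np.sqrt(60))
        np.testing.assert_allclose(band.mu - band.ci_lower,
                                   3.291 * band.sigma / np.sqrt(60))
        # the forced case itself: σ = √60 ⇒ half-width = z
        sigma = np.sqrt(60.0)
        assert 3.291 * sigma / np.sqrt(60) == pytest.approx(3.291)

    def test_z_zero_collapses(self):
        prof = self.make_profile([[0, 1], [2, 3], [4, 5]])
        band = confidence_band(prof, z=0.0)
        np.testing.assert_array_equal(band.ci_lower, band.mu)
        np.testing.assert_array_equal(band.ci_upper, band.mu)

    def test_single_subunit_rejected(self):
        with pytest.raises(ValueError):
            confidence_band(self.make_profile([[1, 2, 3]]))

    def test_probability_extremes(self):
        counts = np.vstack([np.zeros(10, int)] + [np.full(10, 5)] * 9)
        prof = self.make_profile(counts)
        stats = enclosure_probability(prof, confidence_band(prof))
        assert stats.subunit_p[0] == 1.0      # always below the band
        assert stats.subunit_p[1] == 0.0      # never below

    def test_n_sums_match_cellwise_count(self, planted_scenario, planted_map):
        model, dmap = planted_map
        prof = contour_sweep_profile(dmap, element_selections(planted_scenario),
                                     ContourSweep(), model=model)
        band = confidence_band(prof)
        stats = enclosure_probability(prof, band)
        cells_below = int((prof.counts < band.ci_lower[None, :]).sum())
        assert int(stats.subunit_n.sum()) == cells_below

    def test_planted_weight_groups_order_p(self, planted_scenario,
                                           planted_map):
        model, dmap = planted_map
        prof = contour_sweep_profile(dmap, element_selections(planted_scenario),
                                     ContourSweep(), model=model)
        stats = enclosure_probability(prof, confidence_band(prof))
        p = stats.subunit_p
        assert p[:6].mean() > p[6:].mean()  # weighted elements are enclosed

    def test_p_invariant_under_joint_shift(self, planted_scenario,
                                           planted_map):
        model, dmap = planted_map
        sels = element_selections(planted_scenario)
        sweep = ContourSweep()
        prof = contour_sweep_profile(dmap, sels, sweep, model=model)
        shifted_map = dmap.with_grid(dmap.grid + 0.1)
        prof2 = contour_sweep_profile(shifted_map, sels, sweep.shifted(0.1),
                                      model=model)
        np.testing.assert_array_equal(prof.counts, prof2.counts)
        s1 = enclosure_probability(prof, confidence_band(prof))
        s2 = enclosure_probability(prof2, confidence_band(prof2))
        np.testing.assert_array_equal(s1.subunit_p, s2.subunit_p)

    def test_outside_mode_counts_both_tails(self):
        counts = np.vstack([np.zeros(4, int)] + [np.full(4, 2)] * 8
                           + [np.full(4, 4)])
        prof = self.make_profile(counts)
        band = confidence_band(prof)
        lower = enclosure_probability(prof, band, mode="below-lower")
        outside = enclosure_probability(prof, band, mode="outside")
        assert lower.subunit_p[0] == 1.0  # low outlier seen by both modes
        assert outside.subunit_p[9] > lower.subunit_p[9]  # high outlier


class TestMapModelCC:
    def test_self_consistency_cc_one(self, toy_model):
        cfg = MapSimulationConfig(seed=0)
        dmap = simulate_map(toy_model, cfg)
        res = map_model_cc(dmap, toy_model, cfg.nominal_resolution,
                           mask_radius=4.0)
        assert res.correlation == pytest.approx(1.0, abs=1e-6)
        assert res.n_voxels > 0

    def test_negated_map_cc_minus_one(self, toy_model):
        cfg = MapSimulationConfig(seed=0)
        dmap = simulate_map(toy_model, cfg)
        neg = dmap.with_grid(-dmap.grid)
        res = map_model_cc(neg, toy_model, cfg.nominal_resolution, 4.0)
        assert res.correlation == pytest.approx(-1.0, abs=1e-6)

    def test_cc_decreases_with_noise(self, toy_model):
        signal_rms = float(simulate_map(toy_model,
                                        MapSimulationConfig(seed=0)).grid.std())
        ccs = []
        for noise_scale in (0.5, 1.0, 2.0):
            vals = []
            for seed in range(5):
                cfg = MapSimulationConfig(noise_sd=noise_scale * signal_rms,
                                          seed=seed)
                dmap = simulate_map(toy_model, cfg)
                vals.append(map_model_cc(dmap, toy_model, 8.0, 4.0).correlation)
            ccs.append(np.mean(vals))
        assert ccs[0] > ccs[1] > ccs[2]
        assert 0.5 < ccs[1] < 1.0  # noise sd == signal rms
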
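"""SASA, solvent-excluded volumes and interior occupancy."""

import numpy as np
import pytest

from conftest import make_model
from corescaffold.volumetrics import (RadiusTable, SphereMask,
                                      ensemble_volume,
                                      excluded_volume_in_mask,
                                      occupancy_report, sasa)


def ball_model(center=(0, 0, 0), element="C"):
    return make_model([("A", 1, "GLY", "CA", element, tuple(center))])


class TestSasa:
    def test_isolated_carbon_analytic(self):
        areas, total = sasa(ball_model(), RadiusTable(), sphere_points=960)
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert total == pytest.approx(expected, rel=0.01)

    def test_disjoint_additivity(self):
        m = make_model([("A", 1, "G", "CA", "C", (0, 0, 0)),
                        ("B", 1, "G", "CA", "C", (100, 0, 0))])
        _, total = sasa(m, RadiusTable())
        _, single = sasa(ball_model(), RadiusTable())
        assert total == pytest.approx(2 * single, rel=1e-9)

    def test_touching_pair_matches_cap_closed_form(self):
        # two equal spheres of radius R = r + probe at distance d lose one
        # spherical cap each: area lost per atom = 2πR(R − d/2)
        r, probe = 1.7, 1.4
        d = 2 * r  # touching vdW spheres
        m = make_model([("A", 1, "G", "CA", "C", (0, 0, 0)),
                        ("B", 1, "G", "CA", "C", (d, 0, 0))])
        _, total = sasa(m, RadiusTable(probe=probe), sphere_points=4000)
        R = r + probe
        expected = 2 * (4 * np.pi * R ** 2 - 2 * np.pi * R * (R - d / 2))
        assert total == pytest.approx(expected, rel=0.02)

    def test_unknown_element_errors(self):
        with pytest.raises(KeyError, match="XX"):
            sasa(ball_model(element="Xx"), RadiusTable())

    def test_sampling_convergence(self, toy_model):
        sub = toy_model.take(np.arange(60))
        _, coarse = sasa(sub, RadiusTable(), sphere_points=240)
        _, fine = sasa(sub, RadiusTable(), sphere_points=960)
        assert abs(coarse - fine) / fine < 0.01


class TestExcludedVolume:
    def test_isolated_ball_analytic(self):
        radii = RadiusTable(radii={"C": 10.0}, probe=0.0)
        mask = SphereMask(radius=20.0, spacing=0.5)
        v = excluded_volume_in_mask(ball_model(), radii, mask)
        assert v == pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)

    def test_empty_model_zero(self):
        from corescaffold.model import AtomModel
        assert excluded_volume_in_mask([AtomModel.empty()], RadiusTable(),
                                       SphereMask(radius=20, spacing=1)) == 0.0

    def test_small_atom_fraction_matches_finer_grid(self):
        radii = RadiusTable(radii={"C": 2.0}, probe=0.0)
        mask_c = SphereMask(radius=20.0, spacing=1.0)
        mask_f = SphereMask(radius=20.0, spacing=0.25)
        vc = excluded_volume_in_mask(ball_model(), radii, mask_c)
        vf = excluded_volume_in_mask(ball_model(), radii, mask_f)
        assert vc == pytest.approx(vf, rel=0.06)
        assert vf == pytest.approx(4 / 3 * np.pi * 8, rel=0.02)

    def test_probe_closing_recovers_ball(self):
        # dilate-by-probe then erode-by-probe leaves an isolated sphere's
        # volume unchanged up to grid error
        radii0 = RadiusTable(radii={"C": 6.0}, probe=0.0)
        radii14 = RadiusTable(radii={"C": 6.0}, probe=1.4)
        mask = SphereMask(radius=15.0, spacing=0.5)
        v0 = excluded_volume_in_mask(ball_model(), radii0, mask)
        v14 = excluded_volume_in_mask(ball_model(), radii14, mask)
        assert v14 == pytest.approx(v0, rel=0.03)

    def test_grid_halving_convergence(self):
        # a coarse-sphere chain — the geometry the interior-occupancy and
        # ensemble-volume paths actually integrate
        from corescaffold.synth import EnsembleConfig, generate_disordered_ensemble
        chain = generate_disordered_ensemble(
            EnsembleConfig(n_models=1, n_residues=8, seed=4))[0]
        radii = RadiusTable(probe=1.4)
        center = tuple(chain.coord.mean(axis=0))
        v1 = excluded_volume_in_mask(
            chain, radii, SphereMask(center, radius=25, spacing=0.5), 3.0)
        v2 = excluded_volume_in_mask(
            chain, radii, SphereMask(center, radius=25, spacing=0.25), 3.0)
        assert abs(v1 - v2) / v2 < 0.02
        # and the probe-closed sphere, where the analytic answer is exact
        b1 = excluded_volume_in_mask(
            ball_model(), RadiusTable(radii={"C": 6.0}, probe=1.4),
            SphereMask(radius=15, spacing=0.5))
        b2 = excluded_volume_in_mask(
            ball_model(), RadiusTable(radii={"C": 6.0}, probe=1.4),
            SphereMask(radius=15, spacing=0.25))
        assert abs(b1 - b2) / b2 < 0.02

    def test_spacing_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            SphereMask(radius=20.0, spacing=2.0)


class TestEnsembleVolume:
    def test_single_model_sd_zero(self):
        mean, sd, vols = ensemble_volume([ball_model()], RadiusTable(),
                                         SphereMask(radius=20, spacing=1),
                                         residue_radius=3.0)
        assert sd == 0.0 and mean == vols[0] and mean > 0

    def test_rigid_translation_invariance(self):
        chain = make_model([("A", i, "G", "CA", "C", (i * 3.8, 0, 0))
                            for i in range(5)])
        mask = SphereMask(radius=40, spacing=1.0)
        mean, sd, vols = ensemble_volume(
            [chain, chain.translated([0, 12, 0])], RadiusTable(), mask, 3.0)
        assert vols[0] == pytest.approx(vols[1], rel=0.02)

    def test_subsampling_consistency(self):
        from corescaffold.synth import EnsembleConfig, generate_disordered_ensemble
        cfg = EnsembleConfig(n_models=60, n_residues=15,
                             start_anchor=(0.0, 0.0, 0.0),
                             end_anchor=(30.0, 0.0, 0.0), seed=4)
        ens = generate_disordered_ensemble(cfg)
        mask = SphereMask(radius=40, spacing=1.9)
        mean_all, sd_all, _ = ensemble_volume(ens, RadiusTable(), mask, 3.0)
        mean_sub, _, _ = ensemble_volume(ens[:20], RadiusTable(), mask, 3.0)
        assert abs(mean_sub - mean_all) < 3 * sd_all / np.sqrt(20)


class TestOccupancyReport:
    def test_empty_component_gives_empty_fraction_one(self):
        from corescaffold.model import AtomModel
        rep = occupancy_report({"x": AtomModel.empty()}, RadiusTable(),
                               SphereMask(radius=20, spacing=1))
        assert rep.empty_fraction == 1.0
        assert rep.component_fraction["x"] == 0.0

    def test_half_filling_ball(self):
        # ball of radius 20/2^(1/3) occupies half the mask volume
        r = 20.0 / 2 ** (1 / 3)
        radii = RadiusTable(radii={"C": r}, probe=0.0)
        rep = occupancy_report({"ball": ball_model()}, radii,
                               SphereMask(radius=20.0, spacing=0.5))
        assert rep.occupied_fraction == pytest.approx(0.5, rel=0.02)

    def test_full_overlap_union_semantics(self):
        radii = RadiusTable(radii={"C": 5.0}, probe=0.0)
        mask = SphereMask(radius=20, spacing=0.5)
        solo = occupancy_report({"a": ball_model()}, radii, mask)
        both = occupancy_report({"a": ball_model(), "b": ball_model()},
                                radii, mask)
        assert both.occupied_fraction == pytest.approx(solo.occupied_fraction)
        total = sum(both.component_fraction.values()) + both.empty_fraction
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_fractions_sum_to_one(self, toy_model):
        from corescaffold.model import Selection, select_atoms
        interior = select_atoms(toy_model, Selection(
            chain_ids={c for c in toy_model.chains() if c.islower()}))
        rep = occupancy_report({"interior": interior}, RadiusTable(),
                               SphereMask(radius=55, spacing=2.0),
                               atom_radius={"interior": 3.0})
        total = sum(rep.component_fraction.values()) + rep.empty_fraction
        assert total == pytest.approx(1.0, abs=1e-6)
        assert 0 < rep.occupied_fraction < 1

    def test_occupancy_monotone_in_atoms(self):
        radii = RadiusTable(probe=0.0)
        mask = SphereMask(radius=20, spacing=1.0)
        one = occupancy_report({"c": ball_model()}, radii, mask)
        two = occupancy_report(
            {"c": make_model([("A", 1, "G", "CA", "C", (0, 0, 0)),
                              ("A", 2, "G", "CA", "C", (8, 0, 0))])},
            radii, mask)
        assert two.occupied_fraction >= one.occupied_fraction

    def test_name_collision_impossible_by_construction(self):
        # dict keys are unique; the guard still rejects programmatic abuse
        with pytest.raises(ValueError):
            occupancy_report({}, RadiusTable(), SphereMask(radius=20, spacing=1))
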
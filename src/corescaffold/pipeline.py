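"""Headline analyses chaining the stages end to end.

Three orchestrated runs mirror the study's core quantitative claims:

* **Enclosure by proximity** — distances from every outer subunit to its
  nearest interior partner, proximity grouping, per-subunit enclosure
  probability from the contour sweep, and a rank-sum comparison of the two
  groups.
* **Interior occupancy** — component-wise solvent-excluded volumes inside
  a spherical interior mask, including a disordered-chain ensemble term.
* **Pose screening** — restraint/clash/BSA ranking of candidate poses of a
  mobile domain against a receptor.

Defaults mirror the study constants: contour sweep 0.015–0.052 step
0.0005, z = 3.291, interior sphere radius 80 Å, probe 1.4 Å, proximity
bounds 55/70/75 Å, restraint bounds 10–25 Å.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enclosure import (ContourSweep, DEFAULT_Z, confidence_band,
                        contour_sweep_profile, enclosure_probability)
from .geometry import (GROUP1, GROUP2, GroupBounds, GroupComparison,
                       classify_groups, compare_group_probabilities,
                       nearest_partner_distances)
from .interface import PartnerSplit, RestraintSpec, rank_poses
from .model import AtomModel, Selection, select_atoms
from .synth import (AssemblyScenario, EnsembleConfig, MapSimulationConfig,
                    build_toy_assembly, core_anchor_positions,
                    element_selections, generate_disordered_ensemble,
                    interior_anchor_positions, make_pose_set, simulate_map)
from .volumetrics import RadiusTable, SphereMask, occupancy_report

__all__ = [
    "RunConfig",
    "run_enclosure_by_proximity",
    "run_occupancy",
    "run_pose_screen",
]


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run (defaults = study constants)."""

    seed: int = 0
    # enclosure sweep
    sweep_min: float = 0.015
    sweep_max: float = 0.052
    sweep_step: float = 0.0005
    z: float = DEFAULT_Z
    # proximity bounds (Å)
    group1_lo: float = 55.0
    group1_hi: float = 70.0
    group2_threshold: float = 75.0
    # interior mask
    mask_radius: float = 80.0
    mask_spacing: float = 0.5
    probe_radius: float = 1.4
    # restraint (Å)
    restraint_lower: float = 10.0
    restraint_upper: float = 25.0
    # toy-scenario geometry for the proximity analysis: a 20-subunit shell
    # over a 4-trimer tetrahedral interior gives distance shells at ~45,
    # ~61 and ~81 Å, populating both proximity groups under the bounds
    n_core_subunits: int = 20
    shell_radius: float = 85.0
    interior_radius: float = 40.0
    map_noise_sd: float = 0.002
    out_dir: Optional[str] = None

    def sweep(self) -> ContourSweep:
        return ContourSweep(self.sweep_min, self.sweep_max, self.sweep_step)

    def bounds(self) -> GroupBounds:
        return GroupBounds(self.group1_lo, self.group1_hi,
                           self.group2_threshold)

    def write_resolved(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass
class ProximityResult:
    table: pd.DataFrame          # subunit, distance, partner, group, n, N, p
    comparison: Optional[GroupComparison]
    scenario: AssemblyScenario


def _planted_scenario(cfg: RunConfig) -> tuple[AssemblyScenario, list]:
    """Scenario whose element weights encode the planted proximity effect:
    subunits at or below the proximal distance range lack the enclosing
    density (weight 0), distal ones carry it (weight 1)."""
    base = AssemblyScenario(n_core_subunits=cfg.n_core_subunits,
                            shell_radius=cfg.shell_radius,
                            interior_radius=cfg.interior_radius,
                            seed=cfg.seed)
    model = build_toy_assembly(base)
    assignments = nearest_partner_distances(core_anchor_positions(model),
                                            interior_anchor_positions(model))
    classify_groups(assignments, cfg.bounds())
    weights = [0.0 if a.distance <= cfg.group1_hi else 1.0
               for a in assignments]
    scenario = dataclasses.replace(base, element_weights=weights)
    return scenario, assignments


def run_enclosure_by_proximity(cfg: RunConfig = RunConfig(),
                               scenario: Optional[AssemblyScenario] = None,
                               ) -> ProximityResult:
    """Joined per-subunit table of proximity group and enclosure probability.

    With no explicit scenario, a planted one is generated in which proximal
    subunits lack the enclosing density — the configuration the grouped
    comparison is designed to detect."""
    if scenario is None:
        scenario, assignments = _planted_scenario(cfg)
    else:
        model0 = build_toy_assembly(scenario)
        assignments = nearest_partner_distances(
            core_anchor_positions(model0), interior_anchor_positions(model0))
        classify_groups(assignments, cfg.bounds())
    model = build_toy_assembly(scenario)
    map_cfg = MapSimulationConfig(noise_sd=cfg.map_noise_sd, seed=cfg.seed)
    dmap = simulate_map(model, map_cfg, scenario.weight_by_chain)
    profile = contour_sweep_profile(dmap, element_selections(scenario),
                                    cfg.sweep(), model=model)
    stats = enclosure_probability(profile, confidence_band(profile, cfg.z))
    p_by = stats.p_by_subunit()
    by_id = {a.subunit_id: a for a in assignments}
    rows = []
    for sid in stats.subunit_ids:
        a = by_id[sid]
        rows.append(dict(subunit=sid, distance=a.distance,
                         nearest_partner=a.nearest_partner, group=a.group,
                         n=int(stats.subunit_n[stats.subunit_ids.index(sid)]),
                         N=stats.n_levels, p=p_by[sid]))
    table = pd.DataFrame(rows)
    labels = {a.subunit_id: a.group for a in assignments}
    comparison = None
    if any(v == GROUP1 for v in labels.values()) and \
            any(v == GROUP2 for v in labels.values()):
        comparison = compare_group_probabilities(p_by, labels)
    result = ProximityResult(table=table, comparison=comparison,
                             scenario=scenario)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.write_resolved(out / "config.json")
        table.to_csv(out / "enclosure_by_proximity.csv", index=False)
        if comparison is not None:
            comparison.summaries.to_csv(out / "group_summaries.csv")
    return result


def run_occupancy(cfg: RunConfig = RunConfig(),
                  include_ensemble: bool = True,
                  ensemble_models: int = 30):
    """Interior occupancy of the toy assembly within the spherical mask.

    Components: the interior trimers ("interior") and, optionally, a
    disordered-chain ensemble anchored between two interior vertices
    ("flexible"). The outer shell lies outside the mask by construction.
    The mask radius is scaled to sit inside the toy shell."""
    scenario = AssemblyScenario(seed=cfg.seed)
    model = build_toy_assembly(scenario)
    interior_chains = {c for c in model.chains() if c.islower()}
    interior = select_atoms(model, Selection(chain_ids=interior_chains))
    mask_radius = min(cfg.mask_radius, scenario.shell_radius * 0.75)
    mask = SphereMask(center=(0, 0, 0), radius=mask_radius,
                      spacing=max(cfg.mask_spacing, mask_radius / 40))
    radii = RadiusTable(probe=cfg.probe_radius)
    components: dict = {"interior": interior}
    atom_radius = {"interior": 3.0}
    if include_ensemble and len(interior):
        anchors = interior_anchor_positions(model)
        keys = sorted(anchors)
        ens_cfg = EnsembleConfig(n_models=ensemble_models, n_residues=30,
                                 start_anchor=tuple(anchors[keys[0]]),
                                 end_anchor=tuple(anchors[keys[3]])
                                 if len(keys) > 3 else None,
                                 seed=cfg.seed)
        components["flexible"] = generate_disordered_ensemble(ens_cfg)
        atom_radius["flexible"] = 3.0
    report = occupancy_report(components, radii, mask,
                              atom_radius=atom_radius)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.write_resolved(out / "config.json")
        (out / "occupancy.json").write_text(json.dumps({
            "mask_volume_A3": report.mask_volume,
            "component_volume_A3": report.component_volume,
            "component_fraction": report.component_fraction,
            "occupied_fraction": report.occupied_fraction,
            "empty_fraction": report.empty_fraction,
        }, indent=2))
    return report


def run_pose_screen(cfg: RunConfig = RunConfig(),
                    poses: Optional[Sequence[AtomModel]] = None
                    ) -> pd.DataFrame:
    """Rank candidate poses by restraint satisfaction, clashes and BSA."""
    if poses is None:
        poses, _ = make_pose_set(seed=cfg.seed)
    if not poses:
        raise ValueError("no poses to screen")
    spec = RestraintSpec(atom_a=("L", 75, "CA"), atom_b=("E", 387, "CB"),
                         lower=cfg.restraint_lower, upper=cfg.restraint_upper)
    split = PartnerSplit({"receptor": {"E"}, "ligand": {"L"}})
    table = rank_poses(list(poses), spec, split)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.write_resolved(out / "config.json")
        table.to_csv(out / "pose_ranking.csv")
    return table
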
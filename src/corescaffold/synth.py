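"""Synthetic study-condition generators.

This module builds the scaled-down stand-ins on which every pipeline stage
is exercised: a hollow symmetric assembly of rigid pseudo-subunits with an
interior set of trimers (mimicking a 60-mer transacetylase core housing
twelve binding-protein monomers as four tetrahedral trimers), simulated
density maps with a per-subunit "flexible element" of controllable weight,
self-avoiding disordered-chain ensembles, hyperbolic (Michaelis–Menten)
rate tables, and alignments with a planted per-column conservation profile.

Every generator is a pure function of its configuration: the same seed
yields bitwise-identical output. Planted truths (element weights, K_M and
V_max, conservation profile) are exposed so that downstream recovery tests
can compare estimates against them.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .density import DensityMap
from .model import AtomModel, Selection, concat_models

__all__ = [
    "AssemblyScenario",
    "MapSimulationConfig",
    "EnsembleConfig",
    "PackingError",
    "GenerationError",
    "build_toy_assembly",
    "random_enclosure_scenario",
    "make_pose_set",
    "element_selections",
    "core_anchor_positions",
    "interior_anchor_positions",
    "simulate_map",
    "map_sigma",
    "gaussian_density_at",
    "generate_disordered_ensemble",
    "simulate_kinetics_data",
    "simulate_alignment",
]

# residue-name tags used by the toy builder
RIGID_TAG = "COR"
ELEMENT_TAG = "FLX"
ELEMENT_RES_START = 500
CORE_ANCHOR_RES = 251   # mirrors the outer-subunit anchor residue
INTERIOR_ANCHOR_RES = 271  # mirrors the interior-monomer anchor residue

_CORE_CHAINS = string.ascii_uppercase + "0123456789"
_INTERIOR_CHAINS = string.ascii_lowercase


class PackingError(ValueError):
    """Subunits overlap beyond tolerance for the requested geometry."""


class GenerationError(RuntimeError):
    """Chain growth failed after the bounded number of retries."""


@dataclass
class AssemblyScenario:
    """Geometry and seeds for one toy core-scaffold assembly.

    Defaults are the scaled-down study conditions used throughout the test
    suite: 12 outer subunits on an 80 Å shell with 4 interior trimers at
    45 Å, 30 rigid pseudo-atoms and a 20-atom flexible element per subunit.
    """

    n_core_subunits: int = 12
    subunit_atom_count: int = 30
    shell_radius: float = 80.0
    interior_trimers: bool = True
    n_interior_trimers: int = 4
    interior_radius: float = 45.0
    element_atom_count: int = 20
    element_weights: Optional[Sequence[float]] = None
    seed: int = 0
    blob_sd: float = 3.0
    element_offset: float = 10.0
    trimer_spread: float = 5.0

    def __post_init__(self) -> None:
        if self.shell_radius <= 0 or self.interior_radius <= 0:
            raise ValueError("radii must be positive")
        if self.element_weights is None:
            self.element_weights = tuple(1.0 for _ in range(self.n_core_subunits))
        self.element_weights = tuple(float(w) for w in self.element_weights)
        if len(self.element_weights) != self.n_core_subunits:
            raise ValueError("element_weights length must equal n_core_subunits")
        if any(not 0.0 <= w <= 1.0 for w in self.element_weights):
            raise ValueError("element weights must lie in [0, 1]")

    @property
    def core_chain_ids(self) -> list[str]:
        return list(_CORE_CHAINS[: self.n_core_subunits])

    @property
    def weight_by_chain(self) -> dict[str, float]:
        return dict(zip(self.core_chain_ids, self.element_weights))


@dataclass
class MapSimulationConfig:
    """Parameters of the Gaussian map simulator.

    ``nominal_resolution`` sets the per-atom Gaussian width through
    σ = resolution / (π √2); noise is white Gaussian in map units.
    """

    nominal_resolution: float = 8.0
    voxel_size: float = 2.0
    noise_sd: float = 0.0
    padding: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nominal_resolution < 2.0 * self.voxel_size:
            raise ValueError("resolution must be at least twice the voxel size")
        if self.padding < 3.0 * map_sigma(self.nominal_resolution):
            raise ValueError("padding must be at least 3 atom sigmas")


@dataclass
class EnsembleConfig:
    """Self-avoiding Cα-chain ensemble parameters (step = 3.8 Å virtual bond)."""

    n_models: int = 100
    n_residues: int = 50
    step_length: float = 3.8
    start_anchor: tuple[float, float, float] = (0.0, 0.0, 0.0)
    end_anchor: Optional[tuple[float, float, float]] = None
    excluded_radius: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")
        if self.end_anchor is not None:
            span = np.linalg.norm(np.subtract(self.end_anchor, self.start_anchor))
            if span > self.n_residues * self.step_length:
                raise ValueError("anchors farther apart than the chain can span")


def map_sigma(resolution: float) -> float:
    """Gaussian width (Å) for a nominal resolution: σ = d / (π √2)."""
    return resolution / (np.pi * np.sqrt(2.0))


# ---------------------------------------------------------------------------
# assembly builder

def _sphere_points(n: int) -> np.ndarray:
    """n well-spread unit vectors; exact icosahedron for n=12."""
    if n == 12:
        phi = (1 + np.sqrt(5)) / 2
        raw = []
        for s1 in (1, -1):
            for s2 in (1, -1):
                raw.append((0.0, s1 * 1.0, s2 * phi))
                raw.append((s1 * 1.0, s2 * phi, 0.0))
                raw.append((s1 * phi, 0.0, s2 * 1.0))
        pts = np.unique(np.round(np.array(raw), 12), axis=0)
        return pts / np.linalg.norm(pts, axis=1, keepdims=True)
    if n == 20:  # regular dodecahedron: three distance shells to a tetrahedron
        phi = (1 + np.sqrt(5)) / 2
        raw = []
        for s1 in (1, -1):
            for s2 in (1, -1):
                raw.append((0.0, s1 / phi, s2 * phi))
                raw.append((s1 / phi, s2 * phi, 0.0))
                raw.append((s1 * phi, 0.0, s2 / phi))
                raw.append((s1 * 1.0, s2 * 1.0, 1.0))
                raw.append((s1 * 1.0, s2 * 1.0, -1.0))
        pts = np.unique(np.round(np.array(raw), 12), axis=0)
        return pts / np.linalg.norm(pts, axis=1, keepdims=True)
    # Fibonacci lattice
    i = np.arange(n) + 0.5
    theta = np.arccos(1 - 2 * i / n)
    phi_ang = np.pi * (1 + np.sqrt(5)) * i
    return np.column_stack([
        np.sin(theta) * np.cos(phi_ang),
        np.sin(theta) * np.sin(phi_ang),
        np.cos(theta),
    ])


_TETRA = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]) / np.sqrt(3)


def _blob(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    return rng.normal(scale=sd, size=(n, 3))


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1 / 3)
    return v * r[:, None]


def build_toy_assembly(scenario: AssemblyScenario) -> AtomModel:
    """Deterministic hollow assembly with tagged flexible elements.

    Outer subunits sit on a sphere of the shell radius, one chain each; a
    rigid pseudo-atom cluster plus a separately tagged flexible element
    (residue name ``FLX``) displaced radially outward. When interior trimers
    are requested, four trimers of single-chain monomers are placed at
    tetrahedral directions on the interior radius. Anchor Cα atoms mirror
    the outer/interior anchor residues (251 / 271).
    """
    sc = scenario
    if sc.n_core_subunits > len(_CORE_CHAINS):
        raise ValueError("too many core subunits for available chain ids")
    rng = np.random.default_rng(sc.seed)
    dirs = _sphere_points(sc.n_core_subunits)
    sites = dirs * sc.shell_radius

    # packing feasibility: nearest-neighbour site spacing vs blob extent
    if sc.n_core_subunits > 1:
        d = np.linalg.norm(sites[:, None] - sites[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 2.0 * sc.blob_sd:
            raise PackingError(
                f"subunit spacing {d.min():.1f} Å < blob extent "
                f"{2 * sc.blob_sd:.1f} Å: shell radius too small")

    rigid_template = _blob(rng, sc.subunit_atom_count, sc.blob_sd)
    # compact uniform ball: every element atom sits in dense surroundings,
    # so a fully weighted element is enclosed across the whole level sweep
    element_template = _uniform_ball(rng, sc.element_atom_count,
                                     sc.blob_sd * 0.7)

    rows = []
    for k, chain in enumerate(sc.core_chain_ids):
        site = sites[k]
        outward = dirs[k]
        rows.append((chain, CORE_ANCHOR_RES, "ASN", "CA", "C",
                     tuple(site), 1.0, 20.0))
        for j, off in enumerate(rigid_template):
            rows.append((chain, j + 1, RIGID_TAG, "CA", "C",
                         tuple(site + off), 1.0, 20.0))
        elem_center = site + outward * sc.element_offset
        for j, off in enumerate(element_template):
            rows.append((chain, ELEMENT_RES_START + j, ELEMENT_TAG, "CA", "C",
                         tuple(elem_center + off), 1.0, 40.0))

    if sc.interior_trimers and sc.n_core_subunits >= 12:
        mono_template = _blob(rng, max(sc.subunit_atom_count // 3, 4),
                              sc.blob_sd * 0.7)
        chain_iter = iter(_INTERIOR_CHAINS)
        for t in range(sc.n_interior_trimers):
            vdir = _TETRA[t % 4]
            vertex = vdir * sc.interior_radius
            # local triangle perpendicular to the radial direction
            ref = np.array([0.0, 0.0, 1.0])
            if abs(vdir @ ref) > 0.9:
                ref = np.array([1.0, 0.0, 0.0])
            u = np.cross(vdir, ref)
            u /= np.linalg.norm(u)
            w = np.cross(vdir, u)
            for mth in range(3):
                ang = 2 * np.pi * mth / 3
                center = vertex + sc.trimer_spread * (np.cos(ang) * u + np.sin(ang) * w)
                chain = next(chain_iter)
                rows.append((chain, INTERIOR_ANCHOR_RES, "ALA", "CA", "C",
                             tuple(center), 1.0, 20.0))
                for j, off in enumerate(mono_template):
                    rows.append((chain, j + 1, RIGID_TAG, "CA", "C",
                                 tuple(center + off), 1.0, 20.0))

    return AtomModel.from_atoms(rows, model_id=f"toy-assembly-seed{sc.seed}")


def element_selections(scenario: AssemblyScenario) -> dict[str, Selection]:
    """Per-subunit selections of the tagged flexible element."""
    hi = ELEMENT_RES_START + scenario.element_atom_count - 1
    return {
        chain: Selection(chain_ids={chain}, res_range=(ELEMENT_RES_START, hi))
        for chain in scenario.core_chain_ids
    }


def core_anchor_positions(model: AtomModel) -> dict[str, np.ndarray]:
    """Anchor Cα position of each outer subunit, keyed by chain."""
    m = (model.res_id == CORE_ANCHOR_RES) & (model.atom_name == "CA") \
        & (model.res_name == "ASN")
    return {c: xyz for c, xyz in zip(model.chain_id[m], model.coord[m])}


def interior_anchor_positions(model: AtomModel) -> dict[str, np.ndarray]:
    """Anchor Cα position of each interior monomer, keyed by chain."""
    m = (model.res_id == INTERIOR_ANCHOR_RES) & (model.atom_name == "CA") \
        & (model.res_name == "ALA")
    return {c: xyz for c, xyz in zip(model.chain_id[m], model.coord[m])}


def random_enclosure_scenario(seed: int,
                              n_subunits: int = 12) -> AssemblyScenario:
    """Random planted-occupancy scenario for recovery studies.

    A minority of subunits (3–6 of 12) get high element weights (0.7–1.0),
    the rest low ones (0–0.3) — mirroring the situation the enclosure
    statistic is built for, where copies with extra enclosing density are
    the exception in the cohort that defines the confidence band. (When
    enclosed copies are the majority the per-level lower bound drops below
    zero and the statistic saturates; that regime is out of scope for
    recovery tests.)
    """
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 7))
    hi = rng.choice(n_subunits, size=k, replace=False)
    wts = rng.uniform(0.0, 0.3, n_subunits)
    wts[hi] = rng.uniform(0.7, 1.0, k)
    return AssemblyScenario(n_core_subunits=n_subunits,
                            element_weights=wts, seed=seed)


def make_pose_set(n_poses: int = 20, seed: int = 0
                  ) -> tuple[list[AtomModel], int]:
    """Synthetic docking poses of a small mobile domain against a receptor.

    The receptor (chain E) carries the active-site anchor (Ala387 Cβ); the
    mobile domain (chain L) carries the lipoylated-lysine anchor (Lys75
    Cα). Poses are placed at varying separations: some clash, some sit in
    contact at a restraint-satisfying distance, some drift out of reach.
    Returns (poses, planted_best_index): the planted best pose is in
    contact, clash-free, and restraint-satisfying.
    """
    rng = np.random.default_rng(seed)
    rec_atoms = _uniform_ball(rng, 40, 6.0)
    lig_atoms = _uniform_ball(rng, 15, 3.5)
    anchor_dir = np.array([1.0, 0.0, 0.0])
    cb = anchor_dir * 6.5  # receptor anchor on the surface

    def build(offset: np.ndarray, k: int) -> AtomModel:
        rows = [("E", 387, "ALA", "CB", "C", tuple(cb), 1.0, 20.0)]
        rows += [("E", i + 1, "GLY", "CA", "C", tuple(p), 1.0, 20.0)
                 for i, p in enumerate(rec_atoms)]
        center = cb + offset
        rows.append(("L", 75, "LYS", "CA", "C", tuple(center), 1.0, 20.0))
        rows += [("L", 100 + i, "GLY", "CA", "C", tuple(center + p), 1.0, 20.0)
                 for i, p in enumerate(lig_atoms)]
        return AtomModel.from_atoms(rows, model_id=f"pose-{k}")

    # ligand approaches on a ring perpendicular to the anchor direction, so
    # surface contact and a restraint-satisfying anchor distance can coexist
    def ring_dir() -> np.ndarray:
        u = rng.normal(size=3)
        u -= (u @ anchor_dir) * anchor_dir
        u /= np.linalg.norm(u)
        tilted = u + 0.15 * anchor_dir
        return tilted / np.linalg.norm(tilted)

    poses = []
    best = 0
    for k in range(n_poses):
        kind = k % 4
        if k == 0:
            poses.append(build(ring_dir() * 12.0 - cb, k))  # snug contact
        elif kind == 1:
            poses.append(build(ring_dir() * 6.0 - cb, k))   # buried: clashes
        elif kind == 2:
            poses.append(build(ring_dir() * 35.0 - cb, k))  # out of reach
        else:
            poses.append(build(ring_dir() * 17.0 - cb, k))  # barely touching
    return poses, best


# ---------------------------------------------------------------------------
# map simulation

def _atom_weights(model: AtomModel,
                  element_weights: Optional[Mapping[str, float]]) -> np.ndarray:
    w = np.ones(len(model))
    if element_weights:
        for chain, wt in element_weights.items():
            if not 0.0 <= wt <= 1.0:
                raise ValueError(f"element weight {wt} for chain {chain} "
                                 "outside [0, 1]")
            m = (model.chain_id == chain) & (model.res_name == ELEMENT_TAG)
            w[m] = wt
    return w


def gaussian_density_at(positions: np.ndarray, atom_coords: np.ndarray,
                        weights: np.ndarray, sigma: float) -> np.ndarray:
    """Analytic Σ w·G evaluation at arbitrary points (test oracle)."""
    pos = np.atleast_2d(positions)
    amp = (2 * np.pi * sigma ** 2) ** -1.5
    d2 = ((pos[:, None, :] - atom_coords[None, :, :]) ** 2).sum(axis=-1)
    return amp * (weights[None, :] * np.exp(-d2 / (2 * sigma ** 2))).sum(axis=1)


def _stamp_gaussians(grid: np.ndarray, coords: np.ndarray, weights: np.ndarray,
                     sigma: float, voxel: float, origin: np.ndarray,
                     cutoff_sigmas: float = 6.0) -> None:
    """Accumulate normalized Gaussians into a ZYX grid in place."""
    nz, ny, nx = grid.shape
    amp = (2 * np.pi * sigma ** 2) ** -1.5
    cut = cutoff_sigmas * sigma
    axes = [np.arange(n) * voxel for n in (nx, ny, nz)]
    for (x, y, z), w in zip(coords, weights):
        if w == 0.0:
            continue
        p = np.array([x, y, z]) - origin
        lo = np.maximum(np.floor((p - cut) / voxel).astype(int), 0)
        hi = np.minimum(np.ceil((p + cut) / voxel).astype(int) + 1,
                        [nx, ny, nz])
        if np.any(lo >= hi):
            continue
        gx = np.exp(-((axes[0][lo[0]:hi[0]] - p[0]) ** 2) / (2 * sigma ** 2))
        gy = np.exp(-((axes[1][lo[1]:hi[1]] - p[1]) ** 2) / (2 * sigma ** 2))
        gz = np.exp(-((axes[2][lo[2]:hi[2]] - p[2]) ** 2) / (2 * sigma ** 2))
        grid[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] += (
            (w * amp) * gz[:, None, None] * gy[None, :, None] * gx[None, None, :])


def simulate_map(model: AtomModel, cfg: MapSimulationConfig,
                 element_weights: Optional[Mapping[str, float]] = None,
                 like: Optional[DensityMap] = None) -> DensityMap:
    """Simulate a density map: Σ_atoms w·G(position, σ), σ = d/(π√2).

    Atoms tagged as a chain's flexible element are scaled by that chain's
    weight; optional white Gaussian noise is added on top. Deterministic
    given ``cfg.seed``.
    """
    if len(model) == 0:
        raise ValueError("cannot simulate a map from an empty model")
    sigma = map_sigma(cfg.nominal_resolution)
    weights = _atom_weights(model, element_weights)
    if like is not None:
        lo = like.origin.copy()
        grid = np.zeros_like(like.grid)
    else:
        lo = model.coord.min(axis=0) - cfg.padding
        hi = model.coord.max(axis=0) + cfg.padding
        shape_xyz = np.ceil((hi - lo) / cfg.voxel_size).astype(int) + 1
        grid = np.zeros((shape_xyz[2], shape_xyz[1], shape_xyz[0]))
    _stamp_gaussians(grid, model.coord, weights, sigma, cfg.voxel_size, lo)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        grid += rng.normal(scale=cfg.noise_sd, size=grid.shape)
    return DensityMap(grid=grid,
                      voxel_size=np.full(3, float(cfg.voxel_size)),
                      origin=lo, origin_rule="synthetic")


# ---------------------------------------------------------------------------
# disordered-chain ensembles

def _grow_chain(cfg: EnsembleConfig, rng: np.random.Generator,
                max_step_tries: int = 200) -> Optional[np.ndarray]:
    n = cfg.n_residues
    b = cfg.step_length
    pos = np.empty((n, 3))
    pos[0] = cfg.start_anchor
    anchor = None if cfg.end_anchor is None else np.asarray(cfg.end_anchor)
    for i in range(1, n):
        steps_left_after = n - 1 - i
        placed = False
        for _ in range(max_step_tries):
            if anchor is None:
                v = rng.normal(size=3)
                v *= b / np.linalg.norm(v)
            else:
                # sample uniformly from the cone of directions keeping the
                # anchor reachable with the remaining steps (biased growth)
                to_anchor = anchor - pos[i - 1]
                d = np.linalg.norm(to_anchor)
                bound = steps_left_after * b if steps_left_after > 0 else b
                if d < 1e-12:
                    v = rng.normal(size=3)
                    v *= b / np.linalg.norm(v)
                else:
                    c_min = (d * d + b * b - bound * bound) / (2 * d * b)
                    c_min = min(max(c_min, -1.0), 1.0)
                    cos_t = rng.uniform(c_min, 1.0)
                    sin_t = np.sqrt(max(1 - cos_t * cos_t, 0.0))
                    phi = rng.uniform(0, 2 * np.pi)
                    ez = to_anchor / d
                    ref = np.array([0.0, 0.0, 1.0])
                    if abs(ez @ ref) > 0.9:
                        ref = np.array([1.0, 0.0, 0.0])
                    ex = np.cross(ez, ref)
                    ex /= np.linalg.norm(ex)
                    ey = np.cross(ez, ex)
                    v = b * (cos_t * ez
                             + sin_t * (np.cos(phi) * ex + np.sin(phi) * ey))
            cand = pos[i - 1] + v
            if i >= 2:
                d2 = ((pos[: i - 1] - cand) ** 2).sum(axis=1)
                if d2.min() < cfg.excluded_radius ** 2:
                    if anchor is None:
                        # whole-chain restart: keeps the unanchored ensemble
                        # exactly uniform over self-avoiding configurations
                        return None
                    continue
            pos[i] = cand
            placed = True
            break
        if not placed:
            return None
    return pos


def generate_disordered_ensemble(cfg: EnsembleConfig,
                                 max_restarts: int = 20000) -> list[AtomModel]:
    """Self-avoiding Cα-only chains with fixed virtual-bond length.

    Chains start at the start anchor; with an end anchor set, growth is
    constrained so the remaining steps can always reach it and the final
    residue lands within one step length of the anchor.
    """
    rng = np.random.default_rng(cfg.seed)
    out = []
    attempts = 0
    for k in range(cfg.n_models):
        pos = None
        for _ in range(max_restarts):
            attempts += 1
            pos = _grow_chain(cfg, rng)
            if pos is not None:
                break
        if pos is None:
            raise GenerationError(
                f"chain growth failed for model {k} after {attempts} attempts")
        rows = [("A", i + 1, "GLY", "CA", "C", tuple(p), 1.0, 30.0)
                for i, p in enumerate(pos)]
        out.append(AtomModel.from_atoms(rows, model_id=f"ens-{cfg.seed}-{k}"))
    return out


# ---------------------------------------------------------------------------
# kinetics and alignments

def simulate_kinetics_data(km: float, vmax: float,
                           substrate_grid: Sequence[float],
                           noise_sd: float = 0.0, replicates: int = 1,
                           seed: int = 0) -> pd.DataFrame:
    """Hyperbolic rate table v = Vmax·S/(Km+S) + noise, one row per replicate."""
    if km <= 0 or vmax <= 0:
        raise ValueError("km and vmax must be positive")
    rng = np.random.default_rng(seed)
    s = np.asarray(substrate_grid, dtype=float)
    rows = []
    for rep in range(replicates):
        v = vmax * s / (km + s)
        if noise_sd > 0:
            v = v + rng.normal(scale=noise_sd, size=len(s))
        for si, vi in zip(s, v):
            rows.append((si, vi, rep))
    return pd.DataFrame(rows, columns=["substrate_uM", "rate", "replicate"])


_AA = "ACDEFGHIKLMNPQRSTVWY"


def simulate_alignment(reference: str, n_sequences: int,
                       conservation_profile: Sequence[float], seed: int = 0):
    """Alignment whose columns match the reference with planted probability.

    Substitutions are uniform over the 19 other residues. Returns an
    :class:`~corescaffold.conservation.MSA` containing the reference (id
    ``ref``) plus ``n_sequences`` sampled sequences.
    """
    from .conservation import MSA

    profile = np.asarray(conservation_profile, dtype=float)
    if len(profile) != len(reference):
        raise ValueError("profile length must equal reference length")
    rng = np.random.default_rng(seed)
    seqs = {"ref": reference}
    others = {a: [b for b in _AA if b != a] for a in _AA}
    for i in range(n_sequences):
        chars = []
        for j, a in enumerate(reference):
            if rng.random() < profile[j]:
                chars.append(a)
            else:
                pool = others.get(a, list(_AA))
                chars.append(pool[rng.integers(len(pool))])
        seqs[f"seq{i:05d}"] = "".join(chars)
    return MSA(sequences=seqs, reference_id="ref")
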
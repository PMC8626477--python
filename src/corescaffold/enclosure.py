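"""Contour-sweep density-enclosure statistics and map–model correlation.

The central question: at a given display contour level, how many atoms of a
flexible element fall *outside* the rendered density? Sweeping the level
over a fixed range for every symmetry-related subunit yields a matrix of
uncovered-atom counts. Across the M copies a per-level confidence band

    CI = μ ± z·σ/√M        (z = 3.291 by default)

is formed, and each subunit's enclosure probability is

    p = n / N

where n is the number of levels at which that subunit's count lies strictly
below the CI lower bound (fewer uncovered atoms than expected ⇒ extra
density enclosing the element) and N is the number of levels probed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .density import DensityMap
from .model import AtomModel, Selection, select_atoms
from .synth import _stamp_gaussians, map_sigma

__all__ = [
    "ContourSweep",
    "EnclosureProfile",
    "EnclosureStats",
    "CCResult",
    "map_values_at",
    "count_uncovered_atoms",
    "contour_sweep_profile",
    "confidence_band",
    "enclosure_probability",
    "map_model_cc",
]

DEFAULT_Z = 3.291  # per-level band half-width multiplier


@dataclass
class ContourSweep:
    """Inclusive level sweep: count = floor((max−min)/step) + 1."""

    minimum: float = 0.015
    maximum: float = 0.052
    step: float = 0.0005

    def __post_init__(self) -> None:
        if not self.minimum < self.maximum:
            raise ValueError("sweep minimum must be below maximum")
        if self.step <= 0:
            raise ValueError("sweep step must be positive")

    @property
    def n_levels(self) -> int:
        return int(np.floor((self.maximum - self.minimum) / self.step + 1e-9)) + 1

    @property
    def levels(self) -> np.ndarray:
        return self.minimum + self.step * np.arange(self.n_levels)

    def shifted(self, delta: float) -> "ContourSweep":
        return ContourSweep(self.minimum + delta, self.maximum + delta, self.step)


@dataclass
class EnclosureProfile:
    """Uncovered-atom counts, one row per subunit, one column per level."""

    subunit_ids: list
    levels: np.ndarray
    counts: np.ndarray  # (n_subunits, n_levels) int
    atoms_per_subunit: int

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.subunit_ids), len(self.levels)):
            raise ValueError("counts shape mismatch")
        if self.counts.min(initial=0) < 0 or \
                self.counts.max(initial=0) > self.atoms_per_subunit:
            raise ValueError("counts outside [0, atoms_per_subunit]")
        if np.any(np.diff(self.counts, axis=1) < 0):
            raise ValueError("uncovered counts must be non-decreasing in level")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.T, index=pd.Index(self.levels, name="level"),
                            columns=self.subunit_ids)


@dataclass
class EnclosureStats:
    """Per-level band and (after :func:`enclosure_probability`) per-subunit p."""

    z: float
    m_subunits: int
    levels: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_levels: int
    subunit_ids: Optional[list] = None
    subunit_n: Optional[np.ndarray] = None
    subunit_p: Optional[np.ndarray] = None

    def p_by_subunit(self) -> dict:
        if self.subunit_p is None:
            raise ValueError("probabilities not computed yet")
        return dict(zip(self.subunit_ids, self.subunit_p))


@dataclass
class CCResult:
    correlation: float
    mask_radius: float
    n_voxels: int


def map_values_at(dmap: DensityMap, positions: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear map values at physical positions; out-of-box → −inf, flagged."""
    return dmap.values_at(positions)


def count_uncovered_atoms(dmap: DensityMap, atoms: AtomModel,
                          level: float) -> int:
    """Atoms whose interpolated map value is strictly below ``level``.

    Equality counts as covered. An empty selection is an error — it would
    conflate "no element modeled" with "fully covered".
    """
    if len(atoms) == 0:
        raise ValueError("empty atom selection in coverage count")
    vals, _ = dmap.values_at(atoms.coord)
    return int(np.sum(vals < level))


def contour_sweep_profile(
    dmap: DensityMap,
    elements: Mapping[str, Union[AtomModel, Selection]],
    sweep: ContourSweep,
    model: Optional[AtomModel] = None,
) -> EnclosureProfile:
    """Uncovered-count matrix over all subunits and contour levels.

    ``elements`` maps subunit id → element atoms (or a Selection applied to
    ``model``). All subunits must carry the same element atom count, since
    raw counts are only comparable across copies of the same element.
    """
    resolved: dict[str, AtomModel] = {}
    for sid, obj in elements.items():
        if isinstance(obj, Selection):
            if model is None:
                raise ValueError("Selection elements require a model")
            obj = select_atoms(model, obj)
        if len(obj) == 0:
            raise ValueError(f"subunit {sid}: empty element selection")
        resolved[sid] = obj
    counts_per = {len(m) for m in resolved.values()}
    if len(counts_per) != 1:
        raise ValueError(
            f"unequal element atom counts across subunits ({sorted(counts_per)}); "
            "normalize the selections to a common atom set, or compare "
            "fractions instead of raw counts")
    n_atoms = counts_per.pop()
    levels = sweep.levels
    subunit_ids = list(resolved)
    counts = np.empty((len(subunit_ids), len(levels)), dtype=np.int64)
    for i, sid in enumerate(subunit_ids):
        vals, _ = dmap.values_at(resolved[sid].coord)
        counts[i] = (vals[:, None] < levels[None, :]).sum(axis=0)
    return EnclosureProfile(subunit_ids=subunit_ids, levels=levels,
                            counts=counts, atoms_per_subunit=n_atoms)


def confidence_band(profile: EnclosureProfile, z: float = DEFAULT_Z
                    ) -> EnclosureStats:
    """Per-level μ, σ (sample sd) and the band μ ± z·σ/√M across subunits."""
    m = len(profile.subunit_ids)
    if m < 2:
        raise ValueError("confidence band needs at least 2 subunits")
    mu = profile.counts.mean(axis=0)
    sigma = profile.counts.std(axis=0, ddof=1)
    half = z * sigma / np.sqrt(m)
    return EnclosureStats(z=z, m_subunits=m, levels=profile.levels.copy(),
                          mu=mu, sigma=sigma, ci_lower=mu - half,
                          ci_upper=mu + half, n_levels=len(profile.levels))


def enclosure_probability(profile: EnclosureProfile, band: EnclosureStats,
                          mode: str = "below-lower") -> EnclosureStats:
    """Per-subunit enclosure probability p = n/N.

    ``mode='below-lower'`` (default): n counts levels where the subunit's
    uncovered count is strictly below the CI lower bound. ``mode='outside'``
    counts levels strictly outside the band on either side.
    """
    if band.n_levels != len(profile.levels) or \
            band.m_subunits != len(profile.subunit_ids):
        raise ValueError("band was not computed on this profile")
    below = profile.counts < band.ci_lower[None, :]
    if mode == "below-lower":
        hits = below
    elif mode == "outside":
        hits = below | (profile.counts > band.ci_upper[None, :])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = hits.sum(axis=1)
    return EnclosureStats(
        z=band.z, m_subunits=band.m_subunits, levels=band.levels,
        mu=band.mu, sigma=band.sigma, ci_lower=band.ci_lower,
        ci_upper=band.ci_upper, n_levels=band.n_levels,
        subunit_ids=list(profile.subunit_ids),
        subunit_n=n.astype(np.int64),
        subunit_p=n / band.n_levels,
    )


def map_model_cc(dmap: DensityMap, model: AtomModel, resolution: float,
                 mask_radius: float = 3.0) -> CCResult:
    """Masked Pearson correlation between a map and a model-simulated map.

    The model is rendered on the experimental grid with the package's
    Gaussian convention (σ = resolution/(π√2), unit weights); the
    correlation runs over voxels within ``mask_radius`` Å of any model atom.
    """
    if len(model) == 0:
        raise ValueError("empty model")
    nz, ny, nx = dmap.grid.shape
    sim = np.zeros_like(dmap.grid)
    vx, vy, vz = dmap.voxel_size
    if not (abs(vx - vy) < 1e-9 and abs(vy - vz) < 1e-9):
        raise ValueError("map_model_cc requires cubic voxels")
    _stamp_gaussians(sim, model.coord, np.ones(len(model)),
                     map_sigma(resolution), float(vx), dmap.origin)

    mask = np.zeros(dmap.grid.shape, dtype=bool)
    r_vox = mask_radius / float(vx)
    rad = int(np.ceil(r_vox))
    ax = np.arange(-rad, rad + 1)
    ball = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
            + ax[None, None, :] ** 2) <= r_vox ** 2
    idx = np.round((model.coord - dmap.origin) / dmap.voxel_size).astype(int)
    for ix, iy, iz in idx:
        lo = np.array([iz, iy, ix]) - rad
        hi = lo + 2 * rad + 1
        slo = np.maximum(lo, 0)
        shi = np.minimum(hi, dmap.grid.shape)
        if np.any(slo >= shi):
            continue
        blo = slo - lo
        bhi = blo + (shi - slo)
        mask[slo[0]:shi[0], slo[1]:shi[1], slo[2]:shi[2]] |= \
            ball[blo[0]:bhi[0], blo[1]:bhi[1], blo[2]:bhi[2]]
    nvox = int(mask.sum())
    if nvox == 0:
        raise ValueError("empty correlation mask — model outside the map?")
    a = dmap.grid[mask]
    b = sim[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise ValueError("zero variance inside the correlation mask")
    cc = float((a * b).sum() / denom)
    return CCResult(correlation=cc, mask_radius=mask_radius, n_voxels=nvox)
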
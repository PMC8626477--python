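"""Solvent-accessible surface area, solvent-excluded volumes and interior
occupancy of a spherical mask.

SASA uses Shrake–Rupley sphere-point sampling on the probe-extended radii.
Solvent-excluded (molecular) volume is computed on a boolean voxel grid by
morphological closing: dilate the van der Waals spheres by the probe
radius, then erode by the probe (via a Euclidean distance transform), which
reproduces molecular-surface volume semantics to grid accuracy. The
interior occupancy report intersects component volumes with a spherical
mask (80 Å radius by default) and accounts each voxel once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from ._tables import VDW_RADII
from .model import AtomModel, concat_models

__all__ = [
    "RadiusTable",
    "SphereMask",
    "OccupancyReport",
    "sasa",
    "excluded_volume_in_mask",
    "ensemble_volume",
    "occupancy_report",
]


@dataclass
class RadiusTable:
    """Element → vdW radius (Å) plus the solvent probe radius (1.4 Å)."""

    radii: dict = field(default_factory=lambda: dict(VDW_RADII))
    probe: float = 1.4

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("all radii must be positive")
        if self.probe < 0:
            raise ValueError("probe radius must be non-negative")

    def lookup(self, elements: Sequence[str]) -> np.ndarray:
        missing = sorted({str(e).upper() for e in elements}
                         - set(self.radii))
        if missing:
            raise KeyError(f"elements missing from radius table: {missing}")
        return np.array([self.radii[str(e).upper()] for e in elements])


@dataclass
class SphereMask:
    """Spherical interior mask (radius 80 Å default, grid spacing 0.5 Å)."""

    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    radius: float = 80.0
    spacing: float = 0.5

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("mask radius must be positive")
        if self.spacing > self.radius / 20:
            raise ValueError(
                f"grid spacing {self.spacing} too coarse for radius "
                f"{self.radius} (must be <= radius/20)")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius ** 3


@dataclass
class OccupancyReport:
    mask_volume: float
    component_volume: dict
    component_fraction: dict
    occupied_fraction: float
    empty_fraction: float
    spacing: float

    def fractions(self) -> dict:
        out = dict(self.component_fraction)
        out["empty"] = self.empty_fraction
        return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    z = 1 - 2 * i / n
    theta = np.pi * (1 + np.sqrt(5)) * i
    r = np.sqrt(np.maximum(1 - z * z, 0.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(model: AtomModel, radii: RadiusTable = RadiusTable(),
         sphere_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake–Rupley SASA: (per-atom areas Ų, total Ų).

    Test points on each atom's probe-extended sphere are accessible when no
    other atom's probe-extended sphere contains them."""
    if len(model) == 0:
        return np.empty(0), 0.0
    r = radii.lookup(model.element) + radii.probe
    pts = _fibonacci_sphere(sphere_points)
    coords = model.coord
    tree = cKDTree(coords)
    rmax = r.max()
    areas = np.empty(len(model))
    for i in range(len(model)):
        test = coords[i] + r[i] * pts
        nbr = tree.query_ball_point(coords[i], r[i] + rmax)
        nbr = [j for j in nbr if j != i]
        if nbr:
            d2 = ((test[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (r[nbr] ** 2)[None, :]).any(axis=1)
        else:
            buried = np.zeros(sphere_points, dtype=bool)
        frac = 1.0 - buried.mean()
        areas[i] = frac * 4.0 * np.pi * r[i] ** 2
    return areas, float(areas.sum())


def _as_models(obj: Union[AtomModel, Sequence[AtomModel]]) -> list[AtomModel]:
    if isinstance(obj, AtomModel):
        return [obj]
    return list(obj)


def _occupied_grid(models: Sequence[AtomModel], atom_radii: list[np.ndarray],
                   mask: SphereMask, probe: float) -> tuple[np.ndarray, float]:
    """Boolean SES-occupancy grid over the mask's bounding box.

    Morphological closing with sub-voxel accuracy: an exact margin field
    m(v) = min_i(|v − x_i| − r_i) is stamped on the lattice; the probe-
    dilated region is {m ≤ probe}, and the probe erosion corrects the
    voxelized distance transform by the margin excess of the nearest
    background voxel (exact for smooth boundaries, first-order otherwise).
    Grid is padded so erosion near the borders is correct."""
    h = mask.spacing
    c = np.asarray(mask.center, dtype=float)
    band = 4.0 * h  # margin knowledge beyond the dilated surface
    pad = probe + band + 2 * h
    lo = c - mask.radius - pad
    n = int(np.ceil((2 * (mask.radius + pad)) / h)) + 1
    # voxel centers
    ax = lo[0] + h * np.arange(n)
    ay = lo[1] + h * np.arange(n)
    az = lo[2] + h * np.arange(n)
    margin = np.full((n, n, n), np.inf)  # z, y, x
    for m, rr in zip(models, atom_radii):
        for (x, y, z), r in zip(m.coord, rr):
            R = r + probe + band
            ix0 = max(int(np.floor((x - R - lo[0]) / h)), 0)
            ix1 = min(int(np.ceil((x + R - lo[0]) / h)) + 1, n)
            iy0 = max(int(np.floor((y - R - lo[1]) / h)), 0)
            iy1 = min(int(np.ceil((y + R - lo[1]) / h)) + 1, n)
            iz0 = max(int(np.floor((z - R - lo[2]) / h)), 0)
            iz1 = min(int(np.ceil((z + R - lo[2]) / h)) + 1, n)
            if ix0 >= ix1 or iy0 >= iy1 or iz0 >= iz1:
                continue
            dx2 = (ax[ix0:ix1] - x) ** 2
            dy2 = (ay[iy0:iy1] - y) ** 2
            dz2 = (az[iz0:iz1] - z) ** 2
            d = np.sqrt(dz2[:, None, None] + dy2[None, :, None]
                        + dx2[None, None, :])
            sub = margin[iz0:iz1, iy0:iy1, ix0:ix1]
            np.minimum(sub, d - r, out=sub)
    dil = margin <= probe
    if probe > 0 and dil.any():
        # Erosion via probe witnesses: a point v is outside the closed
        # surface iff some probe position w with clearance m(w) ≥ probe has
        # |w − v| < probe; by 1-Lipschitz continuity of the margin field it
        # suffices to scan lattice witnesses u with m(u) ∈ (probe,
        # probe + band] and carve the ball of radius m(u) around each.
        witness = (~dil) & (margin <= probe + band)
        reach = np.zeros_like(dil)
        uz, uy, ux = np.nonzero(witness)
        radii_w = margin[uz, uy, ux]
        kmax = int(np.ceil((probe + band) / h))
        off = np.arange(-kmax, kmax + 1)
        d_off = np.sqrt(off[:, None, None] ** 2 + off[None, :, None] ** 2
                        + off[None, None, :] ** 2) * h
        for z, y, x, rw in zip(uz, uy, ux, radii_w):
            k = int(np.ceil(rw / h))
            z0, y0, x0 = max(z - k, 0), max(y - k, 0), max(x - k, 0)
            z1, y1, x1 = min(z + k + 1, n), min(y + k + 1, n), min(x + k + 1, n)
            c0 = kmax - (z - z0), kmax - (y - y0), kmax - (x - x0)
            sub = d_off[c0[0]:c0[0] + (z1 - z0), c0[1]:c0[1] + (y1 - y0),
                        c0[2]:c0[2] + (x1 - x0)]
            reach[z0:z1, y0:y1, x0:x1] |= sub < rw
        ses = dil & ~reach
        del reach, witness
    else:
        ses = dil
    # intersect with the spherical mask
    dxx = (ax - c[0]) ** 2
    dyy = (ay - c[1]) ** 2
    dzz = (az - c[2]) ** 2
    sphere = (dzz[:, None, None] + dyy[None, :, None]
              + dxx[None, None, :]) <= mask.radius ** 2
    return ses & sphere, h ** 3


def excluded_volume_in_mask(models: Union[AtomModel, Sequence[AtomModel]],
                            radii: RadiusTable, mask: SphereMask,
                            atom_radius: Optional[float] = None) -> float:
    """Solvent-excluded volume (Å³) of the union of ``models`` inside the mask.

    ``atom_radius`` overrides the per-element radii with a uniform value
    (used for coarse Cα-only chains)."""
    models = [m for m in _as_models(models) if len(m)]
    if not models:
        return 0.0
    if atom_radius is not None:
        rr = [np.full(len(m), float(atom_radius)) for m in models]
    else:
        rr = [radii.lookup(m.element) for m in models]
    grid, vvox = _occupied_grid(models, rr, mask, radii.probe)
    return float(grid.sum()) * vvox


def ensemble_volume(ensemble: Sequence[AtomModel], radii: RadiusTable,
                    mask: SphereMask, residue_radius: float = 3.0
                    ) -> tuple[float, float, np.ndarray]:
    """Per-model coarse excluded volume of a Cα ensemble inside the mask.

    Each residue is a sphere of ``residue_radius`` on its Cα. Returns
    (mean, sd, per-model volumes); sd uses the M−1 denominator (0 for a
    single model)."""
    if not ensemble:
        raise ValueError("empty ensemble")
    vols = np.array([
        excluded_volume_in_mask(m, radii, mask, atom_radius=residue_radius)
        for m in ensemble
    ])
    sd = float(vols.std(ddof=1)) if len(vols) > 1 else 0.0
    return float(vols.mean()), sd, vols


def occupancy_report(components: Mapping[str, Union[AtomModel, Sequence[AtomModel]]],
                     radii: RadiusTable, mask: SphereMask,
                     atom_radius: Optional[Mapping[str, float]] = None
                     ) -> OccupancyReport:
    """Component-wise interior occupancy on one shared grid.

    Component volumes are union volumes of that component's models. For the
    fractions, any voxel claimed by several components is split equally
    among them, so the fractions plus the empty fraction sum to one and no
    voxel is counted twice. ``atom_radius`` may give a uniform radius per
    component (e.g. for Cα-only ensembles)."""
    if not components:
        raise ValueError("at least one component required")
    names = list(components)
    if len(set(names)) != len(names):
        raise ValueError("component name collision")
    grids = {}
    vvox = None
    for name in names:
        models = [m for m in _as_models(components[name]) if len(m)]
        ar = (atom_radius or {}).get(name)
        if not models:
            grids[name] = None
            continue
        if ar is not None:
            rr = [np.full(len(m), float(ar)) for m in models]
        else:
            rr = [radii.lookup(m.element) for m in models]
        grids[name], vvox = _occupied_grid(models, rr, mask, radii.probe)
    if vvox is None:  # all components empty: still need the mask volume
        h = mask.spacing
        vvox = h ** 3
        shape = None
    claim = None
    for g in grids.values():
        if g is not None:
            claim = g.astype(np.int32) if claim is None else claim + g
    mask_vox = None
    # mask voxel count from a reference grid (rebuild if every component empty)
    if claim is not None:
        shape = claim.shape
    # count mask voxels analytically on the same lattice
    h = mask.spacing
    c = np.asarray(mask.center, dtype=float)
    pad = radii.probe + 2 * h
    lo = c - mask.radius - pad
    n = int(np.ceil((2 * (mask.radius + pad)) / h)) + 1
    ax = lo[0] + h * np.arange(n)
    ay = lo[1] + h * np.arange(n)
    az = lo[2] + h * np.arange(n)
    sphere = ((az - c[2]) ** 2)[:, None, None] + \
             ((ay - c[1]) ** 2)[None, :, None] + \
             ((ax - c[0]) ** 2)[None, None, :] <= mask.radius ** 2
    mask_vox = int(sphere.sum())
    mask_volume = mask_vox * h ** 3

    comp_volume = {}
    comp_fraction = {}
    union_vox = 0
    if claim is not None:
        union_vox = int((claim > 0).sum())
    for name in names:
        g = grids[name]
        if g is None:
            comp_volume[name] = 0.0
            comp_fraction[name] = 0.0
        else:
            comp_volume[name] = float(g.sum()) * h ** 3
            with np.errstate(divide="ignore", invalid="ignore"):
                share = np.where(claim > 0, g / np.maximum(claim, 1), 0.0)
            comp_fraction[name] = float(share.sum()) / mask_vox
    occupied = union_vox / mask_vox
    report = OccupancyReport(
        mask_volume=mask_volume,
        component_volume=comp_volume,
        component_fraction=comp_fraction,
        occupied_fraction=float(occupied),
        empty_fraction=float(1.0 - occupied),
        spacing=h,
    )
    total = sum(report.component_fraction.values()) + report.empty_fraction
    assert abs(total - 1.0) < 1e-6, "occupancy fractions must sum to 1"
    return report
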
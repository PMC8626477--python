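"""Reading and writing of structure (PDB/mmCIF) and density (MRC/CCP4) files.

All parsing is delegated to gemmi; this module converts between gemmi's
hierarchy/grid objects and the package's flat :class:`~corescaffold.model.AtomModel`
and :class:`~corescaffold.density.DensityMap` containers.

Conventions
-----------
* First model block only; alternate locations resolved to the highest
  occupancy (ties → first encountered).
* MRC origin: the ORIGIN header fields win; if they are all zero but the
  start indices are not, origin = start × voxel size. The rule that fired is
  recorded on the returned map (``origin_rule``).
* Grids are reordered to canonical ZYX on read regardless of the file's
  MAPC/MAPR/MAPS permutation.
"""

from __future__ import annotations

import os
from typing import Literal

import gemmi
import numpy as np

from .density import DensityMap
from .model import AtomModel

__all__ = [
    "read_structure",
    "write_structure",
    "read_density_map",
    "write_density_map",
]


class FormatError(ValueError):
    """Unreadable or unsupported file content."""


class EmptyModelError(ValueError):
    """A structure file parsed but contained no atoms."""


def _detect_format(path: str, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def read_structure(path, fmt: Literal["pdb", "mmcif", "auto"] = "auto") -> AtomModel:
    """Read a PDB or mmCIF file into an :class:`AtomModel`.

    Only the first model block is read. Alternate locations are collapsed to
    the highest-occupancy conformer (tie → first encountered); insertion
    codes are preserved as part of residue identity.
    """
    fmt = _detect_format(path, fmt)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path!s} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path!s}: no model block")
    st.setup_entities()
    mod = st[0]

    rows = []
    for chain in mod:
        for res in chain:
            # resolve altlocs per atom name: keep highest occupancy
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            kept_order = []
            seen = set()
            for atom in res:
                if atom.name not in seen:
                    seen.add(atom.name)
                    kept_order.append(best[atom.name])
            for atom in kept_order:
                rows.append((
                    chain.name,
                    res.seqid.num,
                    res.name,
                    atom.name,
                    atom.element.name,
                    (atom.pos.x, atom.pos.y, atom.pos.z),
                    atom.occ,
                    atom.b_iso,
                    res.seqid.icode.strip(),
                ))
    if not rows:
        raise EmptyModelError(f"{path!s}: model block contains no atoms")
    cols = list(zip(*rows))
    return AtomModel(
        chain_id=np.array(cols[0], dtype=object),
        res_id=np.array(cols[1]),
        res_name=np.array(cols[2], dtype=object),
        atom_name=np.array(cols[3], dtype=object),
        element=np.array(cols[4], dtype=object),
        coord=np.array(cols[5], dtype=float),
        occupancy=np.array(cols[6], dtype=float),
        b_factor=np.array(cols[7], dtype=float),
        icode=np.array(cols[8], dtype=object),
        model_id=os.path.basename(str(path)),
    )


def _to_gemmi(model: AtomModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    mod = gemmi.Model("1")
    # gemmi's add_* methods copy their argument, so containers must be
    # fully populated bottom-up before insertion
    chains: list[tuple[str, list]] = []
    for i in range(len(model)):
        cid = str(model.chain_id[i])
        rkey = (int(model.res_id[i]), str(model.icode[i]),
                str(model.res_name[i]))
        if not chains or chains[-1][0] != cid:
            chains.append((cid, []))
        residues = chains[-1][1]
        if not residues or residues[-1][0] != rkey:
            residues.append((rkey, []))
        residues[-1][1].append(i)
    for cid, residues in chains:
        chain_obj = gemmi.Chain(cid)
        for (num, icode, rname), atom_idx in residues:
            res_obj = gemmi.Residue()
            res_obj.name = rname
            res_obj.seqid = gemmi.SeqId(num, icode or " ")
            for i in atom_idx:
                atom = gemmi.Atom()
                atom.name = str(model.atom_name[i])
                atom.element = gemmi.Element(str(model.element[i]))
                atom.pos = gemmi.Position(*model.coord[i])
                atom.occ = float(model.occupancy[i])
                atom.b_iso = float(model.b_factor[i])
                res_obj.add_atom(atom)
            chain_obj.add_residue(res_obj)
        mod.add_chain(chain_obj)
    st.add_model(mod)
    st.setup_entities()
    return st


def write_structure(model: AtomModel, path, fmt: Literal["pdb", "mmcif", "auto"] = "auto") -> None:
    """Write an :class:`AtomModel` as PDB (3-decimal coordinates) or mmCIF."""
    fmt = _detect_format(path, fmt)
    st = _to_gemmi(model)
    if fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def read_density_map(path) -> DensityMap:
    """Read an MRC/CCP4 map (mode 0/1/2) into canonical ZYX order.

    The origin is taken from the ORIGIN header fields; when those are all
    zero but the start indices are not, it falls back to start × voxel.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read {path!s} as MRC/CCP4: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in (0, 1, 2):
        raise FormatError(f"{path!s}: unsupported MRC mode {mode}")
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise FormatError(f"{path!s}: non-orthogonal cell is unsupported")
    starts = [m.header_i32(w) for w in (5, 6, 7)]
    origin_hdr = np.array([m.header_float(w) for w in (50, 51, 52)])
    m.setup(0.0)  # reorder axes to XYZ, fill full cell
    arr_xyz = np.array(m.grid, copy=True)  # (nx, ny, nz)
    nx, ny, nz = arr_xyz.shape
    voxel = np.array([m.grid.unit_cell.a / nx,
                      m.grid.unit_cell.b / ny,
                      m.grid.unit_cell.c / nz])
    if np.any(origin_hdr != 0):
        origin = origin_hdr
        rule = "origin-field"
    elif any(starts):
        origin = np.array(starts, dtype=float) * voxel
        rule = "start-indices"
    else:
        origin = np.zeros(3)
        rule = "origin-field"
    return DensityMap(grid=arr_xyz.T.astype(np.float64), voxel_size=voxel,
                      origin=origin, origin_rule=rule)


def write_density_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC mode 2 with consistent header statistics."""
    arr_xyz = np.ascontiguousarray(dmap.grid.T, dtype=np.float32)
    g = gemmi.FloatGrid(arr_xyz)
    nx, ny, nz = arr_xyz.shape
    vx, vy, vz = dmap.voxel_size
    g.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90)
    g.spacegroup = gemmi.find_spacegroup_by_name("P1")
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))
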
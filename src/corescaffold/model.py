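"""Atomic-model container and selection primitives.

The :class:`AtomModel` is a flat, column-oriented atom table (chains →
residues → atoms) holding coordinates in Å. It is the unit of currency for
every geometric operation in the package; structure files are converted to
and from it by :mod:`corescaffold.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["AtomModel", "Selection", "select_atoms", "concat_models"]

_HYDROGEN = {"H", "D"}


@dataclass
class AtomModel:
    """Flat atom table: parallel arrays, one row per atom.

    Coordinates are in Å in the map's physical frame. Residue numbers are
    author numbering taken verbatim from files; insertion codes are part of
    residue identity (``icode``).
    """

    chain_id: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    occupancy: np.ndarray
    b_factor: np.ndarray
    icode: np.ndarray = None  # type: ignore[assignment]
    model_id: str = "model"

    def __post_init__(self) -> None:
        n = len(self.chain_id)
        self.chain_id = np.asarray(self.chain_id, dtype=object)
        self.res_id = np.asarray(self.res_id, dtype=np.int64)
        self.res_name = np.asarray(self.res_name, dtype=object)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.element = np.asarray(self.element, dtype=object)
        self.coord = np.asarray(self.coord, dtype=float).reshape(n, 3)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        self.b_factor = np.asarray(self.b_factor, dtype=float)
        if self.icode is None:
            self.icode = np.full(n, "", dtype=object)
        else:
            self.icode = np.asarray(self.icode, dtype=object)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates in atom model")

    def __len__(self) -> int:
        return len(self.chain_id)

    @property
    def n_atoms(self) -> int:
        return len(self)

    def chains(self) -> list[str]:
        """Chain identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(c, None)
        return list(seen)

    def take(self, index: np.ndarray) -> "AtomModel":
        """Row subset preserving order."""
        return AtomModel(
            chain_id=self.chain_id[index],
            res_id=self.res_id[index],
            res_name=self.res_name[index],
            atom_name=self.atom_name[index],
            element=self.element[index],
            coord=self.coord[index],
            occupancy=self.occupancy[index],
            b_factor=self.b_factor[index],
            icode=self.icode[index],
            model_id=self.model_id,
        )

    def translated(self, shift: Sequence[float]) -> "AtomModel":
        return replace(self, coord=self.coord + np.asarray(shift, dtype=float))

    @classmethod
    def from_atoms(
        cls,
        rows: Iterable[tuple],
        model_id: str = "model",
    ) -> "AtomModel":
        """Build from rows of (chain, res_id, res_name, atom_name, element,
        (x, y, z), occupancy, b_factor)."""
        rows = list(rows)
        if not rows:
            return cls.empty(model_id)
        cols = list(zip(*rows))
        return cls(
            chain_id=np.array(cols[0], dtype=object),
            res_id=np.array(cols[1]),
            res_name=np.array(cols[2], dtype=object),
            atom_name=np.array(cols[3], dtype=object),
            element=np.array(cols[4], dtype=object),
            coord=np.array(cols[5], dtype=float),
            occupancy=np.array(cols[6], dtype=float),
            b_factor=np.array(cols[7], dtype=float),
            model_id=model_id,
        )

    @classmethod
    def empty(cls, model_id: str = "model") -> "AtomModel":
        z = np.empty(0, dtype=object)
        return cls(
            chain_id=z.copy(), res_id=np.empty(0, dtype=np.int64),
            res_name=z.copy(), atom_name=z.copy(), element=z.copy(),
            coord=np.empty((0, 3)), occupancy=np.empty(0),
            b_factor=np.empty(0), model_id=model_id,
        )


@dataclass
class Selection:
    """Atom-subset criteria. Empty criteria select everything.

    Residue ranges are inclusive on both ends (author numbering).
    ``heavy_only`` drops hydrogen/deuterium.
    """

    chain_ids: Optional[frozenset] = None
    res_range: Optional[tuple[int, int]] = None
    atom_names: Optional[frozenset] = None
    heavy_only: bool = False

    def __post_init__(self) -> None:
        if self.chain_ids is not None:
            self.chain_ids = frozenset(self.chain_ids)
        if self.atom_names is not None:
            self.atom_names = frozenset(self.atom_names)
        if self.res_range is not None:
            lo, hi = self.res_range
            if lo > hi:
                raise ValueError(f"residue range {self.res_range} has lo > hi")

    def mask(self, model: AtomModel) -> np.ndarray:
        m = np.ones(len(model), dtype=bool)
        if self.chain_ids is not None:
            m &= np.isin(model.chain_id, list(self.chain_ids))
        if self.res_range is not None:
            lo, hi = self.res_range
            m &= (model.res_id >= lo) & (model.res_id <= hi)
        if self.atom_names is not None:
            m &= np.isin(model.atom_name, list(self.atom_names))
        if self.heavy_only:
            m &= ~np.isin(model.element, list(_HYDROGEN))
        return m


def select_atoms(model: AtomModel, sel: Selection) -> AtomModel:
    """Subset of ``model`` matching ``sel``, order preserved.

    An empty result is legal, not an error."""
    return model.take(sel.mask(model))


def concat_models(models: Sequence[AtomModel], model_id: str = "model") -> AtomModel:
    """Stack several models into one atom table (chains kept as-is)."""
    models = [m for m in models if len(m)]
    if not models:
        return AtomModel.empty(model_id)
    return AtomModel(
        chain_id=np.concatenate([m.chain_id for m in models]),
        res_id=np.concatenate([m.res_id for m in models]),
        res_name=np.concatenate([m.res_name for m in models]),
        atom_name=np.concatenate([m.atom_name for m in models]),
        element=np.concatenate([m.element for m in models]),
        coord=np.vstack([m.coord for m in models]),
        occupancy=np.concatenate([m.occupancy for m in models]),
        b_factor=np.concatenate([m.b_factor for m in models]),
        icode=np.concatenate([m.icode for m in models]),
        model_id=model_id,
    )
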
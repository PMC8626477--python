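"""Per-column conservation of a reference residue in an alignment.

A position in the reference's ungapped sequence is mapped to its alignment
column, and the residue frequencies of that column are reported over the
non-gap characters (the gap fraction separately). This mirrors the common
workflow of quoting "X% conservation" of a residue of interest relative to
one reference sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio import AlignIO

__all__ = [
    "MSA",
    "read_msa",
    "map_reference_position",
    "column_conservation",
    "conservation_table",
]

GAP = "-"


@dataclass
class MSA:
    """Aligned sequences (gap '-') with a designated reference id."""

    sequences: dict  # id -> aligned string
    reference_id: str

    def __post_init__(self) -> None:
        if self.reference_id not in self.sequences:
            raise ValueError(f"reference {self.reference_id!r} not in alignment")
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) != 1:
            raise ValueError(f"aligned lengths differ: {sorted(lens)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def reference(self) -> str:
        return self.sequences[self.reference_id]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.sequences.items():
                fh.write(f">{sid}\n{seq}\n")


def read_msa(path, reference_id: str, fmt: str = "fasta") -> MSA:
    """Read a FASTA or Clustal alignment (``fmt``: 'fasta' or 'clustal')."""
    aln = AlignIO.read(str(path), fmt)
    seqs = {rec.id: str(rec.seq).upper() for rec in aln}
    return MSA(sequences=seqs, reference_id=reference_id)


def map_reference_position(msa: MSA, position: int) -> int:
    """Alignment column (0-based) of the reference's ``position``-th
    (1-based) non-gap character."""
    if position < 1:
        raise ValueError("positions are 1-based")
    count = 0
    for col, ch in enumerate(msa.reference):
        if ch != GAP:
            count += 1
            if count == position:
                return col
    raise ValueError(
        f"position {position} beyond the reference's ungapped length {count}")


def column_conservation(msa: MSA, column: int, include_gaps: bool = False
                        ) -> dict:
    """Residue → frequency at an alignment column.

    Frequencies are over non-gap characters by default (residue-identity
    percentages); ``include_gaps=True`` keeps gaps in the denominator.
    Case-insensitive; returns the gap fraction under the key ``'-'`` only
    when gaps are included."""
    if not 0 <= column < msa.length:
        raise ValueError(f"column {column} out of range")
    chars = [seq[column].upper() for seq in msa.sequences.values()]
    non_gap = [c for c in chars if c != GAP]
    if not non_gap:
        raise ValueError(f"column {column} is all gaps")
    denom = len(chars) if include_gaps else len(non_gap)
    pool = chars if include_gaps else non_gap
    out: dict[str, float] = {}
    for c in pool:
        out[c] = out.get(c, 0) + 1
    return {c: n / denom for c, n in sorted(out.items())}


def conservation_table(msa: MSA, positions: Sequence[int]) -> pd.DataFrame:
    """Conservation of the reference residue at several ungapped positions.

    One row per position: the alignment column, the reference residue, the
    fraction of sequences matching it, and the most common substitution."""
    rows = []
    for pos in positions:
        col = map_reference_position(msa, pos)
        ref_res = msa.reference[col].upper()
        freqs = column_conservation(msa, col)
        subs = {c: f for c, f in freqs.items() if c != ref_res}
        top_sub, top_frac = ("", 0.0)
        if subs:
            top_sub = max(subs, key=subs.get)
            top_frac = subs[top_sub]
        rows.append(dict(position=pos, column=col, residue=ref_res,
                         conservation=freqs.get(ref_res, 0.0),
                         top_substitution=top_sub,
                         top_substitution_fraction=top_frac))
    return pd.DataFrame(rows)
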
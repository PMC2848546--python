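"""Backbone extraction from PDB files.

Knot detection operates on the Cα trace of a single chain.  This module
reads PDB ATOM records, resolves alternate locations, records chain
breaks (jumps in author numbering), and keeps author numbering —
including negative residue numbers and insertion codes — because all
reported knot boundaries use the numbering of the deposited structure.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["BackboneChain", "read_backbone", "write_backbone_pdb"]


class ChainNotFoundError(KeyError):
    """Requested chain id is absent from the structure."""


class ChainTooShortError(ValueError):
    """Chain has fewer than two Cα atoms."""


class FormatError(ValueError):
    """Input is not parseable PDB."""


@dataclass
class BackboneChain:
    """Ordered Cα trace of one protein chain.

    Attributes
    ----------
    chain_id:
        Author chain identifier.
    residues:
        ``(author_number, insertion_code)`` per residue, file order.
    coords:
        ``(n, 3)`` float array of Cα positions in Å.
    gap_after:
        Indices ``i`` such that the author numbering jumps by more than
        one between residue ``i`` and ``i + 1`` (unresolved residues in
        between; the trace bridges them with a straight segment).
    """

    chain_id: str
    residues: list[tuple[int, str]]
    coords: np.ndarray
    gap_after: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.residues) != len(self.coords):
            raise ValueError("residues and coords length mismatch")
        if len(self.residues) < 2:
            raise ChainTooShortError("chain too short: need >= 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicated (number, insertion code) pair")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_gaps(self) -> bool:
        return bool(self.gap_after)

    def author_range(self) -> tuple[int, int]:
        """First and last author residue numbers of the trace."""
        return self.residues[0][0], self.residues[-1][0]

    def subchain(self, i: int, j: int) -> "BackboneChain":
        """Slice by positional index, keeping author numbering; ``j`` exclusive."""
        return BackboneChain(
            chain_id=self.chain_id,
            residues=self.residues[i:j],
            coords=self.coords[i:j].copy(),
            gap_after={g - i for g in self.gap_after if i <= g < j - 1},
        )


def _coerce_structure(pdb_source) -> gemmi.Structure:
    if isinstance(pdb_source, gemmi.Structure):
        return pdb_source
    if isinstance(pdb_source, io.IOBase) or hasattr(pdb_source, "read"):
        text = pdb_source.read()
        if isinstance(text, bytes):
            text = text.decode()
        return gemmi.read_pdb_string(text)
    s = str(pdb_source)
    if "\n" in s:  # raw PDB text
        return gemmi.read_pdb_string(s)
    path = Path(s)
    if not path.exists():
        raise FileNotFoundError(path)
    return gemmi.read_pdb(str(path))


def read_backbone(pdb_source, chain_id: str) -> BackboneChain:
    """Extract the Cα trace of one chain from a PDB source.

    ``pdb_source`` may be a path, raw PDB text, a file object, or a
    parsed :class:`gemmi.Structure`.  Only ATOM records are considered
    (HETATM Cα, e.g. from ligands, are ignored).  Alternate locations
    resolve to the highest-occupancy conformer, ties broken by file
    order.  A gap is recorded wherever author numbering jumps by more
    than one; the Cα trace simply bridges it, which can matter for the
    detected knot type, so callers surface ``has_gaps`` in reports.
    """
    try:
        structure = _coerce_structure(pdb_source)
    except (FileNotFoundError, ChainNotFoundError):
        raise
    except Exception as exc:  # gemmi raises RuntimeError on bad input
        raise FormatError(f"format error: {exc}") from exc

    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(f"chain not found: {chain_id!r}")

    residues: list[tuple[int, str]] = []
    coords: list[tuple[float, float, float]] = []
    for res in chain:
        if res.het_flag == "H":
            continue
        best = None
        for atom in res:
            if atom.name != "CA":
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is None:
            continue
        icode = res.seqid.icode.strip()
        key = (res.seqid.num, icode)
        if key in dict.fromkeys(residues):
            continue  # duplicate residue record; keep first
        residues.append(key)
        coords.append((best.pos.x, best.pos.y, best.pos.z))

    if len(residues) < 2:
        raise ChainTooShortError(
            f"chain too short: {len(residues)} Cα in chain {chain_id!r}"
        )

    gap_after: set[int] = set()
    for i in range(len(residues) - 1):
        a, ai = residues[i]
        b, bi = residues[i + 1]
        if b - a > 1:
            gap_after.add(i)
    if gap_after:
        warnings.warn(
            f"chain {chain_id!r}: {len(gap_after)} gap(s) in author numbering; "
            "trace bridges them with straight segments",
            stacklevel=2,
        )
    return BackboneChain(chain_id, residues, np.array(coords), gap_after)


def write_backbone_pdb(chain: BackboneChain, path_or_buf) -> None:
    """Write a Cα-only PDB (one ATOM record per residue).

    Used for fixtures and round-trip tests; numbering and insertion
    codes are preserved exactly, coordinates to PDB precision (1e-3 Å).
    """
    lines = []
    for k, ((num, icode), xyz) in enumerate(zip(chain.residues, chain.coords), 1):
        lines.append(
            f"ATOM  {k:5d}  CA  ALA {chain.chain_id:1s}{num:4d}{icode or ' ':1s}"
            f"   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        Path(path_or_buf).write_text(text)
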
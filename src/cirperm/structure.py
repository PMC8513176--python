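"""Single-chain protein structures and circular-permutation rearrangements.

A circular permutation (CP) joins a protein's native termini and opens new
ones at the CP site.  At the sequence level this is a string rotation; at the
structure level it is a reordering of residue records followed by
renumbering.  This module provides the minimal structure container used
throughout the package (ordered residues, Cα-centric geometry), PDB I/O
backed by gemmi, and the pseudo-CP template construction: for CP site ``n``
the first ``n - 1`` residues are moved to the end of the chain and everything
is renumbered starting from 1.

Coordinates are in Å and residue indices are 1-based everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import gemmi
import numpy as np

from ._aa import NONSTANDARD_PARENT, ONE_TO_THREE, THREE_TO_ONE


class StructureError(ValueError):
    """Base class for structure-level input errors."""


class EmptyChainError(StructureError):
    """Raised when the requested chain has no standard ATOM records."""


class IncompleteResidueError(StructureError):
    """Raised when a residue lacks its alpha-carbon."""


class InvalidCPSiteError(StructureError):
    """Raised when a CP site falls outside 1..L."""


#: A CP site is the 1-based serial (on the renumbered native structure) of
#: the residue that becomes the permutant's new N-terminus; 1 means co-linear.
CPSite = int


@dataclass
class Residue:
    """One amino-acid residue: serial, 3-letter name and atom coordinates."""

    serial: int
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.name]

    @property
    def ca(self) -> np.ndarray:
        try:
            return self.atoms["CA"]
        except KeyError:
            raise IncompleteResidueError(
                f"incomplete residue: {self.name} {self.serial} has no CA atom"
            ) from None

    def copy(self) -> "Residue":
        return Residue(self.serial, self.name,
                       {k: v.copy() for k, v in self.atoms.items()})


@dataclass
class Structure:
    """An ordered single-chain list of residues."""

    residues: list[Residue]
    chain_id: str = "A"

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """(L, 3) array of Cα positions in residue order."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def is_ca_only(self) -> bool:
        return all(set(r.atoms) == {"CA"} for r in self.residues)

    def copy(self) -> "Structure":
        return Structure([r.copy() for r in self.residues], self.chain_id)


def structure_from_ca(sequence: str, coords: np.ndarray,
                      chain_id: str = "A") -> Structure:
    """Build a Cα-only structure from a sequence and an (L, 3) array."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(sequence), 3):
        raise StructureError(
            f"coordinate array shape {coords.shape} does not match sequence "
            f"length {len(sequence)}")
    residues = [
        Residue(i + 1, ONE_TO_THREE[aa], {"CA": coords[i].copy()})
        for i, aa in enumerate(sequence)
    ]
    return Structure(residues, chain_id)


def _standard_name(raw: str) -> str | None:
    raw = raw.strip().upper()
    if raw in THREE_TO_ONE:
        return raw
    return NONSTANDARD_PARENT.get(raw)


def parse_structure(pdb_text: str, chain: str = "A") -> Structure:
    """Read one chain from PDB-format text.

    HETATM records are dropped, chemically modified residues with a standard
    parent (e.g. MSE) are mapped to it, and for alternate locations the
    highest-occupancy conformer is kept.  Residues keep their file order and
    author numbering; use :func:`renumber` to normalise serials to 1..L.

    Raises
    ------
    EmptyChainError
        If the chain holds no standard ATOM records.
    IncompleteResidueError
        If a residue has no alpha-carbon.
    StructureError
        For residues that are neither standard nor mappable.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise EmptyChainError(f"empty chain: no ATOM records for chain {chain!r}")
    model = st[0]
    residues: list[Residue] = []
    for ch in model:
        if ch.name != chain:
            continue
        for res in ch:
            if res.het_flag == "H" and res.name not in NONSTANDARD_PARENT:
                continue  # waters, ligands
            name = _standard_name(res.name)
            if name is None:
                raise StructureError(
                    f"nonstandard residue {res.name} {res.seqid.num} has no "
                    f"standard parent amino acid")
            atoms: dict[str, np.ndarray] = {}
            best_occ: dict[str, float] = {}
            for atom in res:
                if atom.element.name == "H":
                    continue
                occ = atom.occ
                if atom.name not in atoms or occ > best_occ[atom.name]:
                    atoms[atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
                    best_occ[atom.name] = occ
            if "CA" not in atoms:
                raise IncompleteResidueError(
                    f"incomplete residue: {name} {res.seqid.num} has no CA atom")
            residues.append(Residue(res.seqid.num, name, atoms))
    if not residues:
        raise EmptyChainError(f"empty chain: no ATOM records for chain {chain!r}")
    return Structure(residues, chain)


def write_pdb(s: Structure) -> str:
    """Serialise to PDB text: chain A, sequential atom serials, 8.3 fields."""
    lines: list[str] = []
    atom_serial = 0
    for res in s.residues:
        for name, xyz in res.atoms.items():
            atom_serial += 1
            pad_name = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {atom_serial:5d} {pad_name}{'':1s}{res.name:>3s} A"
                f"{res.serial:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          "
                f"{name[0]:>2s}")
    lines.append(f"TER   {atom_serial + 1:5d}      "
                 f"{s.residues[-1].name:>3s} A{s.residues[-1].serial:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def renumber(s: Structure) -> Structure:
    """Assign residue serials 1..L in current order (coordinates untouched).

    Atom serials are not stored on the model; :func:`write_pdb` always emits
    them sequentially, so renumbering a structure and writing it yields
    residues 1..L and atoms 1..M.  Idempotent.
    """
    out = s.copy()
    for i, res in enumerate(out.residues, start=1):
        res.serial = i
    return out


def _check_site(n: int, length: int) -> None:
    if not isinstance(n, (int, np.integer)) or not 1 <= n <= length:
        raise InvalidCPSiteError(
            f"invalid CP site {n!r}: must be an integer in 1..{length}")


def make_pseudo_cp_template(s: Structure, site: CPSite) -> Structure:
    """Reorder residues for CP site ``n``: (n..L, 1..n−1), renumbered.

    Moving the first ``n − 1`` residues to the bottom of the file makes the
    native structure's residue order match the permutant's sequence order, so
    the result can serve directly as a comparative-modeling template.
    ``n = 1`` is the co-linear (no permutation) case.  Coordinates and
    residue/atom counts are conserved; only the order changes.
    """
    _check_site(site, len(s))
    out = s.copy()
    out.residues = out.residues[site - 1:] + out.residues[:site - 1]
    return renumber(out)


def cp_sequence(seq: str, n: CPSite) -> str:
    """Rotate a sequence at CP site ``n``: seq[n..L] + seq[1..n−1]."""
    _check_site(n, len(seq))
    return seq[n - 1:] + seq[:n - 1]


def termini_distance(s: Structure) -> float:
    """Euclidean Cα–Cα distance (Å) between the first and last residues."""
    if len(s) < 2:
        raise StructureError("termini distance needs at least two residues")
    return float(np.linalg.norm(s.residues[0].ca - s.residues[-1].ca))
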
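"""Reading protein backbone geometry from PDB files.

The spatial representation operates on the protein backbone only: the
repeating N-CA-C(-O) atoms of each residue. Side chains are deliberately
discarded — the classifier works from coarse 3-D shape, and fine local
detail is noise at the grid resolutions used downstream.

A structure is reduced to a :class:`BackboneTrace`: the ordered backbone
atom positions of the first model, all chains concatenated, heteroatoms
excluded. Only file order matters; author residue numbering, insertion
codes and chain identity are not retained beyond a running residue
ordinal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "BACKBONE_ATOMS",
    "BackboneTrace",
    "EmptyStructureError",
    "parse_pdb",
    "barycenter",
]

#: Atom names of the peptide backbone. The carbonyl oxygen is included by
#: default; pass a reduced set (e.g. ``{"N", "CA", "C"}``) to drop it.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Alternate-location indicators accepted when a residue carries altlocs.
_ACCEPTED_ALTLOCS = (" ", "", "A")


class EmptyStructureError(ValueError):
    """Raised when a PDB file yields no backbone atoms."""


@dataclass(frozen=True)
class BackboneTrace:
    """Ordered backbone-atom point cloud of one structure, in Å.

    Attributes
    ----------
    structure_id:
        Identifier of the source structure (file stem by default).
    residue_indices:
        Running residue ordinal per atom (0-based, non-decreasing).
        This is a file-order counter, not the author's residue number.
    atom_names:
        Backbone atom name per atom (subset of ``{N, CA, C, O}``).
    coords:
        ``(n_atoms, 3)`` float array of Cartesian coordinates in Å.
    """

    structure_id: str
    residue_indices: np.ndarray
    atom_names: tuple[str, ...]
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        res = np.asarray(self.residue_indices, dtype=int)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_indices", res)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        n = coords.shape[0]
        if n == 0:
            raise EmptyStructureError(
                f"structure {self.structure_id!r} has no backbone atoms"
            )
        if len(self.atom_names) != n or res.shape != (n,):
            raise ValueError("atoms, names and residue indices must align")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinate in backbone trace")
        if np.any(np.diff(res) < 0):
            raise ValueError("residue indices must be non-decreasing")
        bad = set(self.atom_names) - BACKBONE_ATOMS
        if bad:
            raise ValueError(f"non-backbone atom names in trace: {sorted(bad)}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return int(self.residue_indices[-1]) + 1


def parse_pdb(
    path: str | Path,
    backbone_atoms: frozenset[str] = BACKBONE_ATOMS,
    structure_id: str | None = None,
) -> BackboneTrace:
    """Extract the ordered backbone trace from a PDB file.

    Keeps ATOM records of the first model whose atom name is in
    ``backbone_atoms``; HETATM records (waters, ligands, ions) are
    excluded. All chains are concatenated in file order — the enzyme is
    treated as a single point cloud. For disordered atoms only the blank
    or 'A' alternate location is kept; occupancy and B-factor are ignored.

    Raises
    ------
    EmptyStructureError
        If no backbone atoms are found (the structure id is named).
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    sid = structure_id if structure_id is not None else path.stem
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure(sid, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise EmptyStructureError(f"structure {sid!r} contains no model")

    names: list[str] = []
    res_idx: list[int] = []
    coords: list[np.ndarray] = []
    ordinal = -1
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":  # HETATM / water
                continue
            ordinal += 1
            for atom in residue.get_unpacked_list():
                if atom.get_altloc() not in _ACCEPTED_ALTLOCS:
                    continue
                name = atom.get_name()
                if name in backbone_atoms:
                    names.append(name)
                    res_idx.append(ordinal)
                    coords.append(atom.get_coord())
    if not coords:
        raise EmptyStructureError(f"structure {sid!r} has no backbone atoms")
    return BackboneTrace(
        structure_id=sid,
        residue_indices=np.asarray(res_idx, dtype=int),
        atom_names=tuple(names),
        coords=np.asarray(coords, dtype=float),
    )


def barycenter(trace: BackboneTrace) -> np.ndarray:
    """Consensus barycenter: unweighted mean of the backbone positions (Å)."""
    return trace.coords.mean(axis=0)
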
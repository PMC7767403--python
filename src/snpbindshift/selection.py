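"""Minimal atom-selection language shared by the analysis stages.

Selections are strings of space-separated clauses joined by ``and``:

* ``all`` / ``heavy`` / ``hydrogen``
* ``protein`` / ``dna`` / ``water`` (classified by residue name)
* ``chain A`` (one or more chain ids, comma-separated)
* ``name N1,O2P`` (atom names)
* ``resid 4`` or ``resid 2-5`` (residue number or range)

Example: ``"heavy and chain A,B"`` selects the DNA duplex heavy atoms in
the generated fixtures.
"""

from __future__ import annotations

import numpy as np

from .structio import Structure

__all__ = ["select", "SelectionError", "classify_residue"]

DNA_RESIDUES = {"DA", "DT", "DG", "DC"}
WATER_RESIDUES = {"HOH", "WAT"}
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class SelectionError(ValueError):
    """A selection string is malformed or matches no atoms."""


def classify_residue(res_name: str) -> str:
    """'dna', 'protein', 'water' or 'other' from a residue name."""
    if res_name in DNA_RESIDUES:
        return "dna"
    if res_name in WATER_RESIDUES:
        return "water"
    if res_name in AMINO_ACIDS:
        return "protein"
    return "other"


def _clause_mask(structure: Structure, clause: str) -> np.ndarray:
    tokens = clause.split()
    if not tokens:
        raise SelectionError("empty selection clause")
    keyword = tokens[0].lower()
    n = structure.n_atoms
    if keyword == "all":
        return np.ones(n, dtype=bool)
    if keyword == "heavy":
        return np.array([not a.is_hydrogen for a in structure.atoms])
    if keyword == "hydrogen":
        return np.array([a.is_hydrogen for a in structure.atoms])
    if keyword in ("protein", "dna", "water"):
        return np.array(
            [classify_residue(a.res_name) == keyword for a in structure.atoms]
        )
    if keyword == "chain":
        if len(tokens) != 2:
            raise SelectionError(f"chain clause needs ids: {clause!r}")
        ids = {c.strip() for c in tokens[1].split(",")}
        return np.array([a.chain_id in ids for a in structure.atoms])
    if keyword == "name":
        if len(tokens) != 2:
            raise SelectionError(f"name clause needs atom names: {clause!r}")
        names = {c.strip() for c in tokens[1].split(",")}
        return np.array([a.name in names for a in structure.atoms])
    if keyword == "resid":
        if len(tokens) != 2:
            raise SelectionError(f"resid clause needs a number or range: {clause!r}")
        spec = tokens[1]
        if "-" in spec:
            lo_s, hi_s = spec.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(spec)
        return np.array([lo <= a.res_seq <= hi for a in structure.atoms])
    raise SelectionError(f"unknown selection keyword {keyword!r}")


def select(structure: Structure, selection: str) -> np.ndarray:
    """Indices of atoms matching ``selection``; raises on an empty match."""
    mask = np.ones(structure.n_atoms, dtype=bool)
    for clause in selection.split(" and "):
        mask &= _clause_mask(structure, clause.strip())
    indices = np.nonzero(mask)[0]
    if indices.size == 0:
        raise SelectionError(f"selection {selection!r} matches no atoms")
    return indices
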
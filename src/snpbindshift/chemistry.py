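"""Fixed hydrogen-bond donor/acceptor chemistry dictionary.

Geometric H-bond criteria say nothing about which atoms may donate or
accept; that chemistry is pinned here, versioned with the package, so
bond counts are reproducible. Covered: the four standard
deoxyribonucleotides (Watson-Crick faces, N7 of the purines, and the
backbone phosphate/ester oxygens), the twenty amino acids (backbone
amide N-H and carbonyl O plus polar side chains), and water.

Atom names follow the PDB v3 convention used throughout the package
(phosphate oxygens ``O1P``/``O2P``, water ``OW``/``HW1``/``HW2``).
"""

from __future__ import annotations

DICTIONARY_VERSION = "1.0"

# Backbone sets shared by all nucleotides / amino acids.
_NUC_BACKBONE_ACCEPTORS = {"O1P", "O2P", "O3'", "O5'", "O4'"}
_AA_BACKBONE_DONORS = {"N"}
_AA_BACKBONE_ACCEPTORS = {"O", "OXT"}

#: residue name -> set of donor heavy-atom names (hydrogens found geometrically)
DONOR_ATOMS: dict[str, set[str]] = {
    "DA": {"N6"},
    "DT": {"N3"},
    "DG": {"N1", "N2"},
    "DC": {"N4"},
    "HOH": {"OW"},
    "WAT": {"OW"},
    # amino acids: side-chain donors; backbone N added below
    "ARG": {"NE", "NH1", "NH2"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "LYS": {"NZ"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TRP": {"NE1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}

#: residue name -> set of acceptor atom names
ACCEPTOR_ATOMS: dict[str, set[str]] = {
    "DA": {"N1", "N3", "N7"} | _NUC_BACKBONE_ACCEPTORS,
    "DT": {"O2", "O4"} | _NUC_BACKBONE_ACCEPTORS,
    "DG": {"O6", "N3", "N7"} | _NUC_BACKBONE_ACCEPTORS,
    "DC": {"N3", "O2"} | _NUC_BACKBONE_ACCEPTORS,
    "HOH": {"OW"},
    "WAT": {"OW"},
    "ASN": {"OD1"},
    "ASP": {"OD1", "OD2"},
    "GLN": {"OE1"},
    "GLU": {"OE1", "OE2"},
    "HIS": {"ND1", "NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}

_AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL"
).split()

for _aa in _AMINO_ACIDS:
    DONOR_ATOMS.setdefault(_aa, set())
    ACCEPTOR_ATOMS.setdefault(_aa, set())
    if _aa != "PRO":  # proline has no backbone N-H
        DONOR_ATOMS[_aa] = DONOR_ATOMS[_aa] | _AA_BACKBONE_DONORS
    ACCEPTOR_ATOMS[_aa] = ACCEPTOR_ATOMS[_aa] | _AA_BACKBONE_ACCEPTORS

#: maximum covalent H-to-heavy attachment distance, Angstrom
H_ATTACH_CUTOFF = 1.2

#: heavy-heavy distances below this are treated as covalent contacts and
#: never reported as hydrogen bonds
COVALENT_CUTOFF = 1.9


def donor_names(res_name: str) -> set[str]:
    return DONOR_ATOMS.get(res_name, set())


def acceptor_names(res_name: str) -> set[str]:
    return ACCEPTOR_ATOMS.get(res_name, set())
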
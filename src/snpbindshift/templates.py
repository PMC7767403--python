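"""Idealized residue geometry templates for the synthetic structure builder.

One fixed internal-coordinate set, versioned with the package. Templates
are deliberately minimal: they carry every hydrogen-bond-relevant atom
(Watson-Crick faces with explicit polar hydrogens, purine N7, backbone
phosphate/ester oxygens, glycosidic nitrogen, C1') at geometry that
satisfies the default H-bond criteria for the canonical pairings —
three bonds for G.C, two for A.T — while omitting cosmetic ring carbons
and their nonpolar hydrogens, which play no role in any analysis stage.

Frame convention: each base-pair "rung" lies in the xy plane with the
helix axis along +z. Base templates below are written for the chain-B
("right") strand facing the partner in -x; chain-A ("left") residues are
the x-mirrored template of their base. Hydrogen-bond rails sit at
y = +1.1, 0.0, -1.1 with donor-acceptor separations of 2.90 A and
collinear donor hydrogens.
"""

from __future__ import annotations

TEMPLATE_VERSION = "1.0"

#: B-form helical rise per base-pair step, Angstrom
RISE = 3.38
#: B-form helical twist per base-pair step, degrees
TWIST = 36.0

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
RESIDUE_NAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}

# Shared sugar-phosphate backbone fragment (right-strand orientation).
_BACKBONE = [
    ("C1'", 4.20, -0.55, 0.00),
    ("O4'", 4.90, 0.60, 0.30),
    ("P", 5.60, -1.10, 0.80),
    ("O1P", 6.70, -0.45, 1.10),
    ("O2P", 5.90, -2.30, 0.40),
    ("O5'", 4.80, -1.55, 1.90),
    ("O3'", 4.55, -1.30, -1.35),
]

#: base letter -> list of (atom name, x, y, z), right-strand orientation
BASE_ATOMS: dict[str, list[tuple[str, float, float, float]]] = {
    "A": [
        ("N9", 3.00, -0.55, 0.00),
        ("N6", 1.45, 1.10, 0.00),
        ("H61", 0.45, 1.10, 0.00),
        ("H62", 1.10, 2.04, 0.00),
        ("N1", 1.45, 0.00, 0.00),
        ("N3", 2.60, -1.30, 0.00),
        ("N7", 2.60, 2.20, 0.00),
    ],
    "T": [
        ("N1", 3.00, -0.55, 0.00),
        ("N3", 1.45, 0.00, 0.00),
        ("H3", 0.45, 0.00, 0.00),
        ("O4", 1.45, 1.10, 0.00),
        ("O2", 1.45, -1.10, 0.00),
    ],
    "G": [
        ("N9", 3.00, -0.55, 0.00),
        ("O6", 1.45, 1.10, 0.00),
        ("N1", 1.45, 0.00, 0.00),
        ("H1", 0.45, 0.00, 0.00),
        ("N2", 1.45, -1.10, 0.00),
        ("H21", 0.45, -1.10, 0.00),
        ("H22", 1.10, -2.04, 0.00),
        ("N7", 2.60, 2.20, 0.00),
        ("N3", 2.60, -1.30, 0.00),
    ],
    "C": [
        ("N1", 3.00, -0.55, 0.00),
        ("N4", 1.45, 1.10, 0.00),
        ("H41", 0.45, 1.10, 0.00),
        ("H42", 1.10, 2.04, 0.00),
        ("N3", 1.45, 0.00, 0.00),
        ("O2", 1.45, -1.10, 0.00),
    ],
}

#: ideal water geometry (hydrogens repositioned by the bridge placer)
WATER_ATOMS = [
    ("OW", 0.00, 0.00, 0.00),
    ("HW1", 0.96, 0.00, 0.00),
    ("HW2", -0.24, 0.93, 0.00),
]


def residue_atoms(base: str, strand: str) -> list[tuple[str, float, float, float]]:
    """Atoms of one nucleotide in the rung frame.

    ``strand`` is ``"right"`` (chain B, template as written) or
    ``"left"`` (chain A, x-mirrored so the Watson-Crick face points +x).
    """
    if base not in BASE_ATOMS:
        raise ValueError(f"unknown base {base!r}; expected one of A, C, G, T")
    atoms = BASE_ATOMS[base] + _BACKBONE
    if strand == "right":
        return list(atoms)
    if strand == "left":
        return [(name, -x, y, z) for name, x, y, z in atoms]
    raise ValueError(f"strand must be 'left' or 'right', got {strand!r}")
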
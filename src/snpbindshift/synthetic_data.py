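"""Synthetic inputs for every pipeline stage.

Everything the analysis consumes can be generated here at desk scale,
with no downloads and no MD engine:

* idealized B-form DNA duplexes (3.38 A rise, 36 deg twist) whose
  Watson-Crick faces carry explicit polar hydrogens and satisfy the
  geometric H-bond criteria (three bonds per G.C pair, two per A.T),
* point mutation of one base pair within its helical frame,
* toy protein-DNA complexes with a hydrogen-bonding interface and a
  placeable bridging water,
* replicate pseudo-trajectories: per-frame Gaussian positional noise on
  heavy atoms (hydrogens ride their heavy atom), with the mutant preset
  given a smaller fluctuation amplitude than wild type,
* replicate AR(1) interaction-energy series for the four systems
  {AT, GC} x {Complex, DNA}.

The ``paper_default`` preset pins the four-system mean energies so that
the noiseless thermodynamic cycle evaluates to exactly -0.800 kcal/mol,
split as -0.700 electrostatic and -0.100 van der Waals — the regime in
which the binding shift is dominated by electrostatics. The ``null``
preset makes the two variants literally identical (same seeds), so the
cycle closes at exactly zero and the rigidity comparison ties.

These generators emulate the statistical character of MD output
(autocorrelated energies, positional fluctuation), not its physics:
there is no force field, no solvent model and no dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from . import templates
from .structio import (
    DEFAULT_SAMPLE_INTERVAL_PS,
    ENVIRONMENTS,
    VARIANTS,
    Atom,
    EnergySeries,
    Structure,
    Trajectory,
)

__all__ = [
    "EnergyPreset",
    "EnergyCell",
    "TrajectoryPreset",
    "SyntheticDataset",
    "build_duplex",
    "mutate_pair",
    "build_toy_complex",
    "place_bridging_water",
    "simulate_trajectory",
    "simulate_energy_series",
    "preset",
    "pair_centroid",
]

_PAIR_CHOICES = ("AT", "GC", "TA", "CG")


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


def _rung_frame(pair_index: int) -> tuple[np.ndarray, float]:
    """Rotation matrix and z offset of 1-based rung ``pair_index``."""
    angle = math.radians((pair_index - 1) * templates.TWIST)
    c, s = math.cos(angle), math.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return rot, (pair_index - 1) * templates.RISE


def _pair_atoms(pair: str, pair_index: int) -> tuple[list, list]:
    """(chain A atom tuples, chain B atom tuples) for one placed rung."""
    left_base, right_base = pair[0], pair[1]
    rot, dz = _rung_frame(pair_index)

    def _place(atoms, res_name):
        placed = []
        for name, x, y, z in atoms:
            vec = rot @ np.array([x, y, z])
            placed.append((name, res_name, (vec[0], vec[1], vec[2] + dz)))
        return placed

    left = _place(
        templates.residue_atoms(left_base, "left"), templates.RESIDUE_NAME[left_base]
    )
    right = _place(
        templates.residue_atoms(right_base, "right"), templates.RESIDUE_NAME[right_base]
    )
    return left, right


def _assemble(per_chain: dict[str, list[tuple[str, str, int, tuple]]], title: str) -> Structure:
    """Build a Structure from {chain: [(name, res_name, res_seq, xyz)]}."""
    atoms: list[Atom] = []
    serial = 1
    for chain_id, entries in per_chain.items():
        for name, res_name, res_seq, xyz in entries:
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    res_name=res_name,
                    res_seq=res_seq,
                    chain_id=chain_id,
                    coords=tuple(float(v) for v in xyz),
                    record="HETATM" if res_name in ("HOH", "WAT") else "ATOM",
                )
            )
            serial += 1
    return Structure(atoms=atoms, title=title)


def build_duplex(sequence: str) -> Structure:
    """Idealized B-form duplex for a chain-A sequence (5'->3').

    The complementary strand is generated automatically; chains are
    labelled A and B with residue ``i`` of each chain forming pair ``i``.
    """
    sequence = sequence.upper()
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - set("ACGT")
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    chain_a: list = []
    chain_b: list = []
    for i, base in enumerate(sequence, start=1):
        pair = base + templates.COMPLEMENT[base]
        left, right = _pair_atoms(pair, i)
        chain_a.extend((name, res, i, xyz) for name, res, xyz in left)
        chain_b.extend((name, res, i, xyz) for name, res, xyz in right)
    return _assemble({"A": chain_a, "B": chain_b}, title=f"idealized duplex {sequence}")


def mutate_pair(duplex: Structure, position: int, new_pair: str) -> Structure:
    """Replace the base pair at 1-based ``position`` with ``new_pair``.

    Both strands' residues at the position are rebuilt from the new
    pair's template in the same helical frame; every other atom keeps
    its coordinates exactly. Works on duplexes (and complexes) built by
    this module, whose rung frames are deterministic.
    """
    if new_pair not in _PAIR_CHOICES:
        raise ValueError(f"new_pair must be one of {_PAIR_CHOICES}")
    dna_seqs = {
        a.res_seq for a in duplex.atoms if a.chain_id == "A" and a.res_name.startswith("D")
    }
    if position not in dna_seqs:
        raise IndexError(
            f"position {position} outside duplex (pairs {min(dna_seqs)}..{max(dna_seqs)})"
        )
    left, right = _pair_atoms(new_pair, position)
    replacements = {"A": left, "B": right}

    per_chain: dict[str, list] = {}
    for a in duplex.atoms:
        entries = per_chain.setdefault(a.chain_id, [])
        if a.chain_id in ("A", "B") and a.res_seq == position:
            continue  # dropped; re-inserted from template below
        entries.append((a.name, a.res_name, a.res_seq, a.coords))
    # splice the new residues back at their sequence position
    for chain_id, new_atoms in replacements.items():
        entries = per_chain[chain_id]
        insert_at = next(
            (k for k, e in enumerate(entries) if e[2] > position), len(entries)
        )
        for offset, (name, res, xyz) in enumerate(new_atoms):
            entries.insert(insert_at + offset, (name, res, position, xyz))
    title = duplex.title + f" [pair {position} -> {new_pair}]"
    return _assemble(per_chain, title=title)


def _find_atom(structure: Structure, chain_id: str, res_seq: int, name: str) -> Atom:
    for a in structure.atoms:
        if a.chain_id == chain_id and a.res_seq == res_seq and a.name == name:
            return a
    raise KeyError(f"atom {chain_id}/{res_seq}/{name} not found")


def pair_centroid(structure: Structure, site: int) -> np.ndarray:
    """Centroid of the heavy atoms of base pair ``site`` (chains A+B)."""
    coords = [
        a.coords
        for a in structure.atoms
        if a.chain_id in ("A", "B") and a.res_seq == site and not a.is_hydrogen
    ]
    if not coords:
        raise KeyError(f"no pair atoms at site {site}")
    return np.asarray(coords, dtype=float).mean(axis=0)


def _radial(xy: np.ndarray) -> np.ndarray:
    u = np.array([xy[0], xy[1], 0.0])
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    return u / norm


def build_toy_complex(duplex: Structure, site: int) -> Structure:
    """Add a minimal two-residue 'protein' chain P contacting the DNA.

    A serine is anchored so its hydroxyl donates a hydrogen bond to the
    chain-B phosphate oxygen O1P of the site residue (a direct
    protein-DNA contact), and an asparagine provides a carbonyl acceptor
    4.6 A outward of the O2P oxygen, leaving room for a bridging water
    between them (:func:`place_bridging_water`).
    """
    o1p = np.array(_find_atom(duplex, "B", site, "O1P").coords)
    o2p = np.array(_find_atom(duplex, "B", site, "O2P").coords)
    u1 = _radial(o1p)
    u2 = _radial(o2p)
    z = np.array([0.0, 0.0, 1.0])
    t1 = np.cross(z, u1)

    og = o1p + 2.9 * u1
    hg = o1p + 1.9 * u1  # collinear: zero H-D-A angle to O1P
    cb = og + 1.5 * u1
    ca = cb + 1.5 * (0.7 * u1 + 0.7 * z)
    n = ca + 1.5 * (0.7 * u1 - 0.7 * z)
    h = n + 1.0 * u1
    c = ca + 1.5 * t1
    o = c + 1.2 * (0.7 * t1 + 0.7 * z)
    ser = [
        ("N", "SER", 1, tuple(n)),
        ("H", "SER", 1, tuple(h)),
        ("CA", "SER", 1, tuple(ca)),
        ("C", "SER", 1, tuple(c)),
        ("O", "SER", 1, tuple(o)),
        ("CB", "SER", 1, tuple(cb)),
        ("OG", "SER", 1, tuple(og)),
        ("HG", "SER", 1, tuple(hg)),
    ]

    od1 = o2p + 4.6 * u2
    cg = od1 + 1.4 * u2
    nd2 = cg + 1.4 * z
    hd21 = nd2 + 1.0 * (0.7 * u2 + 0.7 * z)
    hd22 = nd2 + 1.0 * (0.7 * np.cross(z, u2) + 0.7 * z)
    cb2 = cg + 1.5 * (0.7 * u2 - 0.7 * z)
    ca2 = cb2 + 1.5 * (0.7 * u2 - 0.7 * z)
    n2 = ca2 + 1.5 * np.cross(z, u2)
    h2 = n2 + 1.0 * u2
    c2 = ca2 + 1.5 * u2
    o2 = c2 + 1.2 * (0.7 * u2 - 0.7 * z)
    asn = [
        ("N", "ASN", 2, tuple(n2)),
        ("H", "ASN", 2, tuple(h2)),
        ("CA", "ASN", 2, tuple(ca2)),
        ("C", "ASN", 2, tuple(c2)),
        ("O", "ASN", 2, tuple(o2)),
        ("CB", "ASN", 2, tuple(cb2)),
        ("CG", "ASN", 2, tuple(cg)),
        ("OD1", "ASN", 2, tuple(od1)),
        ("ND2", "ASN", 2, tuple(nd2)),
        ("HD21", "ASN", 2, tuple(hd21)),
        ("HD22", "ASN", 2, tuple(hd22)),
    ]

    per_chain: dict[str, list] = {}
    for a in duplex.atoms:
        per_chain.setdefault(a.chain_id, []).append(
            (a.name, a.res_name, a.res_seq, a.coords)
        )
    per_chain["P"] = ser + asn
    return _assemble(per_chain, title=duplex.title + " + toy TF")


def place_bridging_water(complex_structure: Structure, site: int) -> Structure:
    """Insert one water bridging the protein and the DNA near the site.

    The water oxygen sits on the perpendicular bisector of the DNA
    acceptor (chain-B O2P of the site residue) and the protein acceptor
    (ASN OD1), 2.9 A from each, with one hydrogen aimed collinearly at
    each acceptor — satisfying the default criteria on both sides and
    lying within the 10 A bridge-search radius of the site centroid.
    """
    chains = set(a.chain_id for a in complex_structure.atoms)
    if "P" not in chains:
        raise ValueError("complex has no protein chain P; build_toy_complex first")
    q = np.array(_find_atom(complex_structure, "B", site, "O2P").coords)
    r = np.array(_find_atom(complex_structure, "P", 2, "OD1").coords)
    d = float(np.linalg.norm(r - q))
    if d >= 5.8:
        raise ValueError(
            f"acceptors {d:.2f} A apart: no water can bond both at 2.9 A"
        )
    e = (r - q) / d
    z = np.array([0.0, 0.0, 1.0])
    perp = z - np.dot(z, e) * e
    norm = np.linalg.norm(perp)
    if norm < 1e-9:
        perp = np.array([1.0, 0.0, 0.0]) - e[0] * e
        norm = np.linalg.norm(perp)
    perp /= norm
    h = math.sqrt(max(2.9**2 - (d / 2) ** 2, 0.0))
    ow = (q + r) / 2 + h * perp
    hw1 = ow + (q - ow) / 2.9  # 1.0 A toward the DNA acceptor
    hw2 = ow + (r - ow) / 2.9  # 1.0 A toward the protein acceptor

    center = pair_centroid(complex_structure, site)
    if np.linalg.norm(ow - center) >= 10.0:
        raise ValueError("no feasible bridging-water placement within the site radius")

    per_chain: dict[str, list] = {}
    for a in complex_structure.atoms:
        per_chain.setdefault(a.chain_id, []).append(
            (a.name, a.res_name, a.res_seq, a.coords)
        )
    per_chain["W"] = [
        ("OW", "HOH", 1, tuple(ow)),
        ("HW1", "HOH", 1, tuple(hw1)),
        ("HW2", "HOH", 1, tuple(hw2)),
    ]
    return _assemble(per_chain, title=complex_structure.title + " + bridging water")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryPreset:
    """Gaussian-fluctuation pseudo-trajectory parameters."""

    base: Structure
    sigma: float = 0.5  # per-atom positional fluctuation scale, Angstrom
    n_frames: int = 50
    dt_ps: float = 10.0
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _hydrogen_parents(structure: Structure) -> np.ndarray:
    """For each atom, the index of the heavy atom it rides (itself if heavy)."""
    coords = structure.coordinates()
    heavy = np.array([not a.is_hydrogen for a in structure.atoms])
    heavy_idx = np.nonzero(heavy)[0]
    parents = np.arange(structure.n_atoms)
    for i in np.nonzero(~heavy)[0]:
        d = np.linalg.norm(coords[heavy_idx] - coords[i], axis=1)
        parents[i] = heavy_idx[int(np.argmin(d))]
    return parents


def simulate_trajectory(preset: TrajectoryPreset) -> Trajectory:
    """Frames = base coordinates + iid Gaussian heavy-atom displacements.

    Hydrogens ride their nearest heavy atom (identical displacement), so
    hydrogen-bond geometry stays chemically sane in fluctuating frames.
    Not molecular dynamics: frames are statistically independent.
    """
    base = preset.base.coordinates()
    parents = _hydrogen_parents(preset.base)
    rng = np.random.default_rng(preset.seed)
    n_atoms = preset.base.n_atoms
    disp = rng.normal(0.0, preset.sigma, size=(preset.n_frames, n_atoms, 3))
    frames = base[None, :, :] + disp[:, parents, :]
    return Trajectory(topology=preset.base, frames=frames, dt_ps=preset.dt_ps)


# ---------------------------------------------------------------------------
# Energy series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnergyCell:
    """Stationary AR(1) parameters of one (variant, environment) system."""

    mean_vdw: float
    mean_el: float
    sigma_vdw: float = 1.0
    sigma_el: float = 2.0


@dataclass
class EnergyPreset:
    """Four-system AR(1) energy-series generator settings."""

    cells: dict[tuple[str, str], EnergyCell]
    phi: float = 0.9  # lag-1 autocorrelation of the AR(1) samples
    n_runs: int = 16
    n_samples: int = 10_000
    seed: int = 42
    name: str = "custom"
    mirror_variants: bool = False  # null preset: GC reuses the AT streams

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1:
            raise ValueError("phi must satisfy |phi| < 1")
        for cell in self.cells.values():
            if cell.sigma_vdw < 0 or cell.sigma_el < 0:
                raise ValueError("sigmas must be >= 0")
        missing = [
            (v, e)
            for v in VARIANTS
            for e in ENVIRONMENTS
            if (v, e) not in self.cells
        ]
        if missing:
            raise ValueError(f"preset missing cells: {missing}")


def _ar1(rng: np.random.Generator, mu: float, sigma: float, phi: float, n: int) -> np.ndarray:
    """Stationary AR(1): x_t = mu + phi (x_{t-1} - mu) + eps, sd(x) = sigma."""
    if sigma == 0.0:
        return np.full(n, mu)
    eps_sd = sigma * math.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, eps_sd, size=n)
    eps[0] = rng.normal(0.0, sigma)  # draw x_0 from the stationary law
    centered = lfilter([1.0], [1.0, -phi], eps)
    return mu + centered


def simulate_energy_series(
    preset: EnergyPreset,
    variant: str,
    environment: str,
    run_index: int,
) -> EnergySeries:
    """One run's AR(1) interaction-energy series for one system cell.

    Streams are seeded per (preset seed, run, variant, environment,
    channel); with ``mirror_variants`` both variants share streams, so
    the four-system cycle closes at exactly zero.
    """
    if (variant, environment) not in preset.cells:
        raise KeyError(f"unknown cell {(variant, environment)}")
    cell = preset.cells[(variant, environment)]
    seed_variant = "AT" if preset.mirror_variants else variant
    v_code = VARIANTS.index(seed_variant)
    e_code = ENVIRONMENTS.index(environment)
    series = {}
    for ch_code, (channel, mu, sigma) in enumerate(
        [("vdw", cell.mean_vdw, cell.sigma_vdw), ("el", cell.mean_el, cell.sigma_el)]
    ):
        ss = np.random.SeedSequence([preset.seed, run_index, v_code, e_code, ch_code])
        series[channel] = _ar1(
            np.random.default_rng(ss), mu, sigma, preset.phi, preset.n_samples
        )
    return EnergySeries(
        variant=variant,
        environment=environment,
        e_vdw=series["vdw"],
        e_el=series["el"],
        ligand_label="rSNP base pair",
        sample_interval_ps=DEFAULT_SAMPLE_INTERVAL_PS,
    )


# ---------------------------------------------------------------------------
# Full presets
# ---------------------------------------------------------------------------

#: component deltas pinned so the noiseless cycle gives exactly
#: -0.700 (electrostatic) and -0.100 (van der Waals) kcal/mol
_EL_DELTA = -0.7 / 0.43
_VDW_DELTA = -0.1 / 0.18

_BASE_CELLS = {
    ("AT", "Complex"): EnergyCell(mean_vdw=-100.0, mean_el=-200.0),
    ("AT", "DNA"): EnergyCell(mean_vdw=-90.0, mean_el=-180.0),
    ("GC", "DNA"): EnergyCell(mean_vdw=-90.0, mean_el=-180.0),
    ("GC", "Complex"): EnergyCell(
        mean_vdw=-100.0 + _VDW_DELTA, mean_el=-200.0 + _EL_DELTA
    ),
}

#: wild-type heavy-atom fluctuation scale, Angstrom
WT_SIGMA = 0.5
#: mutant fluctuation scale: 0.7 x wild type (more rigid by construction)
MUT_SIGMA_FACTOR = 0.7

DEFAULT_SEQUENCE = "GCGAAGC"
DEFAULT_SITE = 4  # the A.T pair mutated to C.G


@dataclass
class SyntheticDataset:
    """Everything the four-system pipeline consumes, generated in memory."""

    structures: dict[tuple[str, str], Structure]
    trajectories: dict[tuple[str, str], list[Trajectory]]
    energies: dict[tuple[str, str], list[EnergySeries]]
    energy_preset: EnergyPreset
    site: int
    sequence: str
    name: str


def preset(
    name: str,
    n_runs: int = 16,
    n_samples: int = 10_000,
    n_frames: int = 50,
    seed: int = 42,
    sequence: str = DEFAULT_SEQUENCE,
    site: int = DEFAULT_SITE,
) -> SyntheticDataset:
    """Build a named full dataset: structures, trajectories and energies.

    ``paper_default``: four-system means pinned so the noiseless cycle
    gives -0.800 kcal/mol (-0.700 el, -0.100 vdW); mutant trajectories
    fluctuate at 0.7x the wild-type scale. ``null``: the two variants
    are identical (shared seeds), so every contrast vanishes exactly.
    """
    if name == "paper_default":
        energy_preset = EnergyPreset(
            cells=dict(_BASE_CELLS),
            n_runs=n_runs,
            n_samples=n_samples,
            seed=seed,
            name=name,
        )
        sigmas = {"AT": WT_SIGMA, "GC": WT_SIGMA * MUT_SIGMA_FACTOR}
        mirror = False
    elif name == "null":
        null_cell = EnergyCell(mean_vdw=-90.0, mean_el=-180.0)
        energy_preset = EnergyPreset(
            cells={(v, e): null_cell for v in VARIANTS for e in ENVIRONMENTS},
            n_runs=n_runs,
            n_samples=n_samples,
            seed=seed,
            name=name,
            mirror_variants=True,
        )
        sigmas = {"AT": WT_SIGMA, "GC": WT_SIGMA}
        mirror = True
    else:
        raise ValueError(f"unknown preset {name!r}; choose 'paper_default' or 'null'")

    wt_duplex = build_duplex(sequence)
    wt_complex = place_bridging_water(build_toy_complex(wt_duplex, site), site)
    if mirror:
        # the null dataset carries no mutation at all: the GC systems are
        # exact copies of the AT ones, so every contrast vanishes exactly
        mut_duplex, mut_complex = wt_duplex, wt_complex
    else:
        mut_duplex = mutate_pair(wt_duplex, site, "CG")
        mut_complex = place_bridging_water(build_toy_complex(mut_duplex, site), site)
    structures = {
        ("AT", "DNA"): wt_duplex,
        ("GC", "DNA"): mut_duplex,
        ("AT", "Complex"): wt_complex,
        ("GC", "Complex"): mut_complex,
    }

    trajectories: dict[tuple[str, str], list[Trajectory]] = {}
    for (variant, environment), base in structures.items():
        seed_variant = "AT" if mirror else variant
        v_code = VARIANTS.index(seed_variant)
        e_code = ENVIRONMENTS.index(environment)
        runs = []
        for run in range(n_runs):
            run_seed = np.random.SeedSequence([seed, run, v_code, e_code, 99])
            runs.append(
                simulate_trajectory(
                    TrajectoryPreset(
                        base=base,
                        sigma=sigmas[variant],
                        n_frames=n_frames,
                        seed=run_seed,
                    )
                )
            )
        trajectories[(variant, environment)] = runs

    energies = {
        (v, e): [
            simulate_energy_series(energy_preset, v, e, run) for run in range(n_runs)
        ]
        for v in VARIANTS
        for e in ENVIRONMENTS
    }
    return SyntheticDataset(
        structures=structures,
        trajectories=trajectories,
        energies=energies,
        energy_preset=energy_preset,
        site=site,
        sequence=sequence,
        name=name,
    )
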
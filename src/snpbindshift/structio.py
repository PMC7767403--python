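"""Structure, trajectory and energy-table I/O.

The pipeline exchanges three kinds of data on disk, all plain text:

* structures as fixed-column PDB (``ATOM``/``HETATM``/``TER``/``END``,
  wwPDB v3.3 column layout),
* trajectories as multi-model PDB (``MODEL``/``ENDMDL``), one model per
  frame over a fixed topology, frame spacing carried in a
  ``REMARK   1 DT_PS`` header line,
* per-sample ligand--surrounding interaction energies as comma-delimited
  tables with a ``# key=value`` metadata header.

Units are Angstrom for coordinates, kcal/mol for energies and picoseconds
for times throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "EnergySeries",
    "PDBFormatError",
    "StructuralMismatchError",
    "EnergyTableError",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "read_energy_table",
    "write_energy_table",
]

#: Default energy sampling interval: 10 MD steps at a 2 fs step size.
DEFAULT_SAMPLE_INTERVAL_PS = 0.02

VARIANTS = ("AT", "GC")
ENVIRONMENTS = ("Complex", "DNA")


class PDBFormatError(ValueError):
    """A PDB record could not be parsed; the message names the line."""


class StructuralMismatchError(ValueError):
    """A trajectory model does not match its topology."""


class EnergyTableError(ValueError):
    """An energy table is malformed or lacks required metadata."""


def _infer_element(name: str) -> str:
    """Element symbol from a PDB atom name (first alphabetic character,
    so ``"O1P" -> "O"``, ``"HW1" -> "H"``, ``"C1'" -> "C"``)."""
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus Cartesian coordinates in Angstrom."""

    serial: int
    name: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    element: str = ""
    record: str = "ATOM"

    def __post_init__(self) -> None:
        if not self.element:
            object.__setattr__(self, "element", _infer_element(self.name))
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if self.record not in ("ATOM", "HETATM"):
            raise ValueError(f"record must be ATOM or HETATM, got {self.record!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Structure:
    """An ordered collection of atoms: topology plus one conformation."""

    atoms: list[Atom] = field(default_factory=list)
    title: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serial numbers in structure")
        keys = [(a.chain_id, a.res_seq, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, res_seq, atom name) in structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def with_coordinates(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [
            replace(a, coords=(float(x), float(y), float(z)))
            for a, (x, y, z) in zip(self.atoms, coords)
        ]
        return Structure(atoms=atoms, title=self.title)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


@dataclass
class Trajectory:
    """Ordered frames of coordinates over a fixed topology.

    ``frames`` is (n_frames, n_atoms, 3) in Angstrom; ``dt_ps`` is the
    frame spacing in picoseconds. Frame indices are 0-based in code and
    1-based in written reports.
    """

    topology: Structure
    frames: np.ndarray
    dt_ps: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{self.topology.n_atoms}-atom topology"
            )
        if not self.dt_ps > 0:
            raise ValueError("dt_ps must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class EnergySeries:
    """Per-sample ligand--surrounding interaction energies for one system.

    ``variant`` identifies the ligand base pair (``AT`` wild type, ``GC``
    mutant); ``environment`` the simulation end state (``Complex`` bound,
    ``DNA`` free). Energies are kcal/mol.
    """

    variant: str
    environment: str
    e_vdw: np.ndarray
    e_el: np.ndarray
    ligand_label: str = "rSNP base pair"
    sample_interval_ps: float = DEFAULT_SAMPLE_INTERVAL_PS

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(
                f"environment must be one of {ENVIRONMENTS}, got {self.environment!r}"
            )
        self.e_vdw = np.asarray(self.e_vdw, dtype=float)
        self.e_el = np.asarray(self.e_el, dtype=float)
        if self.e_vdw.ndim != 1 or self.e_el.ndim != 1:
            raise ValueError("energy series must be one-dimensional")
        if len(self.e_vdw) != len(self.e_el):
            raise ValueError("e_vdw and e_el must have equal length")
        if len(self.e_vdw) < 1:
            raise ValueError("energy series must contain at least one sample")
        if not (np.all(np.isfinite(self.e_vdw)) and np.all(np.isfinite(self.e_el))):
            raise ValueError("energy series contain non-finite values")

    def __len__(self) -> int:
        return len(self.e_vdw)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------


def _parse_atom_line(line: str, lineno: int) -> Atom:
    # wwPDB v3.3 fixed columns (1-based): serial 7-11, name 13-16,
    # resName 18-20, chainID 22, resSeq 23-26, x/y/z 31-38/39-46/47-54,
    # element 77-78.
    line = line.rstrip("\n").rstrip("\r")
    record = line[:6].strip()
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21:22].strip() or " "
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"line {lineno}: unparseable {record} record: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    return Atom(
        serial=serial,
        name=name,
        res_name=res_name,
        res_seq=res_seq,
        chain_id=chain_id,
        coords=(x, y, z),
        element=element or _infer_element(name),
        record=record,
    )


def _scan_models(path: Path) -> tuple[str, list[list[Atom]], float | None]:
    """Scan a PDB file into (title, per-model atom lists, dt from header)."""
    title = ""
    dt_ps: float | None = None
    models: list[list[Atom]] = []
    current: list[Atom] = []
    in_model = False
    saw_model_record = False
    with open(path, "r", newline=None) as handle:
        for lineno, raw in enumerate(handle, start=1):
            rec = raw[:6].strip()
            if rec == "TITLE":
                title = (title + " " + raw[10:].strip()).strip()
            elif rec == "REMARK" and "DT_PS" in raw:
                try:
                    dt_ps = float(raw.split("DT_PS", 1)[1].strip())
                except ValueError:
                    warnings.warn(f"line {lineno}: unreadable DT_PS remark ignored")
            elif rec == "MODEL":
                saw_model_record = True
                in_model = True
                current = []
            elif rec == "ENDMDL":
                in_model = False
                models.append(current)
                current = []
            elif rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(raw, lineno))
            # TER / END / other records carry no atoms
    if current:
        # trailing atoms outside MODEL blocks form their own model
        models.append(current)
    if not models and not saw_model_record:
        models = [[]]
    return title, models, dt_ps


def read_pdb(path: str | Path) -> Structure:
    """Read a single-conformation Structure from a PDB file.

    Only the first MODEL of a multi-model file is read (a warning is
    emitted for the rest). Raises :class:`PDBFormatError` naming the line
    on an unparseable record, and ``ValueError`` on an atom-less file.
    """
    path = Path(path)
    title, models, _ = _scan_models(path)
    if len(models) > 1:
        warnings.warn(
            f"{path.name}: {len(models)} models present; reading the first only"
        )
    atoms = models[0]
    if not atoms:
        raise ValueError(f"{path}: no ATOM/HETATM records (empty structure)")
    return Structure(atoms=atoms, title=title)


def _format_atom_line(atom: Atom) -> str:
    name = atom.name
    # short names start in column 14; 4-character names fill 13-16
    padded = name.ljust(4) if len(name) >= 4 else f" {name}".ljust(4)
    x, y, z = atom.coords
    return (
        f"{atom.record:<6}{atom.serial:>5} {padded}"
        f" {atom.res_name:>3} {atom.chain_id:1}{atom.res_seq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {atom.element:>2}"
    )


def _structure_lines(structure: Structure) -> list[str]:
    lines: list[str] = []
    prev_chain: str | None = None
    for atom in structure.atoms:
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        lines.append(_format_atom_line(atom))
        prev_chain = atom.chain_id
    lines.append("TER")
    return lines


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-column PDB (coordinates to 3 decimals)."""
    path = Path(path)
    lines: list[str] = []
    if structure.title:
        lines.append(f"TITLE     {structure.title}")
    lines.extend(_structure_lines(structure))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_trajectory(
    path: str | Path,
    topology: Structure,
    dt_ps: float | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a Trajectory over ``topology``.

    Every MODEL must contain exactly the topology's atoms in topology
    order; a mismatch raises :class:`StructuralMismatchError` naming the
    1-based model index. ``dt_ps`` given by the caller overrides the
    ``REMARK   1 DT_PS`` header; with neither, 1.0 ps is assumed.
    """
    path = Path(path)
    _, models, header_dt = _scan_models(path)
    models = [m for m in models if m]
    if not models:
        raise ValueError(f"{path}: no models with atoms")
    n = topology.n_atoms
    frames = np.empty((len(models), n, 3), dtype=float)
    for i, model in enumerate(models):
        if len(model) != n:
            raise StructuralMismatchError(
                f"{path.name}: model {i + 1} has {len(model)} atoms, "
                f"topology has {n}"
            )
        for j, (atom, ref) in enumerate(zip(model, topology.atoms)):
            if atom.name != ref.name or atom.chain_id != ref.chain_id:
                raise StructuralMismatchError(
                    f"{path.name}: model {i + 1} atom {j + 1} is "
                    f"{atom.chain_id}/{atom.name}, topology has "
                    f"{ref.chain_id}/{ref.name}"
                )
            frames[i, j] = atom.coords
    if dt_ps is None:
        dt_ps = header_dt if header_dt is not None else 1.0
    return Trajectory(topology=topology, frames=frames, dt_ps=dt_ps)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a Trajectory as multi-model PDB with a DT_PS header remark."""
    path = Path(path)
    lines = [f"REMARK   1 DT_PS {traj.dt_ps:g}"]
    for i in range(traj.n_frames):
        lines.append(f"MODEL     {i + 1:>4}")
        frame_struct = traj.topology.with_coordinates(traj.frames[i])
        lines.extend(_structure_lines(frame_struct))
        lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------


def read_energy_table(path: str | Path) -> EnergySeries:
    """Read one system's interaction-energy series from delimited text.

    Layout: ``# key=value`` metadata lines (``variant`` and
    ``environment`` required), a ``sample,e_vdw,e_el`` header row, then
    numeric rows. ``sample_interval_ps`` defaults to 0.02 ps when absent.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    e_vdw: list[float] = []
    e_el: list[float] = []
    with open(path, "r", newline=None) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    meta[key.strip()] = value.strip()
                continue
            if line.lower().replace(" ", "").startswith("sample,"):
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise EnergyTableError(
                    f"{path.name} row {lineno}: expected 3 fields, got {len(parts)}"
                )
            try:
                e_vdw.append(float(parts[1]))
                e_el.append(float(parts[2]))
            except ValueError as exc:
                raise EnergyTableError(
                    f"{path.name} row {lineno}: non-numeric cell: {exc}"
                ) from exc
    for key in ("variant", "environment"):
        if key not in meta:
            raise EnergyTableError(f"{path.name}: missing '# {key}=' metadata line")
    if not e_vdw:
        raise EnergyTableError(f"{path.name}: no data rows")
    return EnergySeries(
        variant=meta["variant"],
        environment=meta["environment"],
        e_vdw=np.array(e_vdw),
        e_el=np.array(e_el),
        ligand_label=meta.get("ligand_label", "rSNP base pair"),
        sample_interval_ps=float(
            meta.get("sample_interval_ps", DEFAULT_SAMPLE_INTERVAL_PS)
        ),
    )


def write_energy_table(series: EnergySeries, path: str | Path) -> None:
    """Write an EnergySeries; numeric values keep full float precision."""
    path = Path(path)
    lines = [
        f"# variant={series.variant}",
        f"# environment={series.environment}",
        f"# ligand_label={series.ligand_label}",
        f"# sample_interval_ps={series.sample_interval_ps!r}",
        "sample,e_vdw,e_el",
    ]
    for i, (v, e) in enumerate(zip(series.e_vdw, series.e_el), start=1):
        lines.append(f"{i},{float(v)!r},{float(e)!r}")
    path.write_text("\n".join(lines) + "\n")
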
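"""Geometric hydrogen-bond and water-bridge detection.

A hydrogen bond exists when the donor--acceptor distance is below 3.0 A
and the angle at the donor between the D->H and D->A vectors is below
20 deg — strictly geometric criteria, applied with strict inequalities
(boundary values excluded). Water-mediated protein-DNA bridges are
waters within a 10 A radius of the variant site that satisfy the same
criteria simultaneously toward at least one protein atom and one DNA
atom (in either donor/acceptor direction).

Which atoms may donate or accept comes from the fixed dictionary in
:mod:`snpbindshift.chemistry`; hydrogens are attached to their donor
heavy atom geometrically (nearest eligible heavy atom within 1.2 A).
Bonds are keyed by (donor heavy atom, acceptor): which of a donor's
hydrogens satisfies the criterion in a given frame does not fragment
one bond into several (rotating water hydrogens keep one identity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import chemistry
from .selection import classify_residue
from .structio import Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBondEvent",
    "WaterBridge",
    "HBondSummary",
    "DonorAcceptorTable",
    "assign_donors_acceptors",
    "detect_hbonds",
    "detect_water_bridges",
    "hbond_statistics",
    "trajectory_hbonds",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Distance/angle cutoffs, both applied as strict inequalities."""

    d_max: float = 3.0  # donor-acceptor distance, Angstrom
    theta_max: float = 20.0  # hydrogen-donor-acceptor angle, degrees

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.theta_max < 90:
            raise ValueError("theta_max must lie in (0, 90) degrees")


@dataclass(frozen=True)
class HBondEvent:
    """One detected donor-H...acceptor contact in one frame.

    Atom fields are indices into the structure's atom list.
    """

    donor: int
    hydrogen: int
    acceptor: int
    frame: int
    distance: float
    angle: float


@dataclass(frozen=True)
class WaterBridge:
    """A water simultaneously H-bonded to protein and DNA in one frame."""

    water_res: tuple[str, int]  # (chain_id, res_seq) of the water
    protein_event: HBondEvent
    dna_event: HBondEvent
    frame: int


@dataclass
class HBondSummary:
    """Occupancy and lifetime statistics for one (donor, acceptor) key."""

    donor_label: str
    acceptor_label: str
    occupancy: float
    mean_duration_ps: float
    n_events: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class DonorAcceptorTable:
    """Resolved donor heavy atoms (with their hydrogens) and acceptors."""

    donors: list[tuple[int, list[int]]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)

    @property
    def n_donor_hydrogens(self) -> int:
        return sum(len(hs) for _, hs in self.donors)


def atom_label(structure: Structure, index: int) -> str:
    a = structure.atoms[index]
    return f"{a.chain_id}/{a.res_name}{a.res_seq}/{a.name}"


def assign_donors_acceptors(structure: Structure) -> DonorAcceptorTable:
    """Resolve donors and acceptors on a structure with explicit polar H.

    Every hydrogen is attached to the nearest heavy atom within 1.2 A; a
    hydrogen with no such neighbour raises a topology ``ValueError``. A
    structure without hydrogens yields zero donors (acceptors are still
    listed) with a warning.
    """
    coords = structure.coordinates()
    heavy_idx = [i for i, a in enumerate(structure.atoms) if not a.is_hydrogen]
    h_idx = [i for i, a in enumerate(structure.atoms) if a.is_hydrogen]

    attached: dict[int, list[int]] = {i: [] for i in heavy_idx}
    if h_idx and heavy_idx:
        heavy_xyz = coords[heavy_idx]
        for h in h_idx:
            d = np.linalg.norm(heavy_xyz - coords[h], axis=1)
            j = int(np.argmin(d))
            if d[j] >= chemistry.H_ATTACH_CUTOFF:
                raise ValueError(
                    f"hydrogen {atom_label(structure, h)} has no heavy atom "
                    f"within {chemistry.H_ATTACH_CUTOFF} A (nearest {d[j]:.2f} A)"
                )
            attached[heavy_idx[j]].append(h)
    elif h_idx and not heavy_idx:
        raise ValueError("structure contains hydrogens but no heavy atoms")

    table = DonorAcceptorTable()
    for i in heavy_idx:
        a = structure.atoms[i]
        if a.name in chemistry.donor_names(a.res_name) and attached[i]:
            table.donors.append((i, sorted(attached[i])))
        if a.name in chemistry.acceptor_names(a.res_name):
            table.acceptors.append(i)
    if not h_idx:
        warnings.warn(
            "structure has no hydrogens: no donors can be resolved "
            "(acceptors are still listed)"
        )
    return table


def detect_hbonds(
    coords: np.ndarray,
    donors: list[tuple[int, list[int]]] | DonorAcceptorTable,
    acceptors: list[int] | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    frame: int = 0,
) -> list[HBondEvent]:
    """All hydrogen bonds in one frame under the geometric criteria.

    ``coords`` is the frame's (n_atoms, 3) array; donors/acceptors come
    from :func:`assign_donors_acceptors` on the matching topology. Pairs
    closer than the covalent cutoff (1.9 A) and donor==acceptor pairs
    are excluded; per (donor, acceptor) key the best-angle hydrogen
    defines the single reported event.
    """
    if isinstance(donors, DonorAcceptorTable):
        if acceptors is not None:
            raise TypeError("pass either a table or separate donor/acceptor lists")
        table = donors
        donors_list, acceptors_list = table.donors, table.acceptors
    else:
        if acceptors is None:
            raise TypeError("acceptors required when donors is a list")
        donors_list, acceptors_list = donors, acceptors
    if not donors_list or not acceptors_list:
        return []

    coords = np.asarray(coords, dtype=float)
    pairs = [(d, h) for d, hs in donors_list for h in hs]
    d_idx = np.array([p[0] for p in pairs])
    h_idx = np.array([p[1] for p in pairs])
    a_idx = np.array(acceptors_list)

    D = coords[d_idx]  # (m, 3)
    H = coords[h_idx]
    A = coords[a_idx]  # (k, 3)

    da = A[None, :, :] - D[:, None, :]  # (m, k, 3)
    dist = np.linalg.norm(da, axis=2)
    dh = H - D  # (m, 3)
    dh_norm = np.linalg.norm(dh, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.einsum("mkx,mx->mk", da, dh) / (dist * dh_norm[:, None])
    cos_theta = np.clip(cos_theta, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_theta))

    ok = (
        (dist < criteria.d_max)
        & (dist >= chemistry.COVALENT_CUTOFF)
        & (angle < criteria.theta_max)
        & (d_idx[:, None] != a_idx[None, :])
    )

    best: dict[tuple[int, int], HBondEvent] = {}
    for m, k in zip(*np.nonzero(ok)):
        key = (int(d_idx[m]), int(a_idx[k]))
        event = HBondEvent(
            donor=key[0],
            hydrogen=int(h_idx[m]),
            acceptor=key[1],
            frame=frame,
            distance=float(dist[m, k]),
            angle=float(angle[m, k]),
        )
        prev = best.get(key)
        if prev is None or event.angle < prev.angle:
            best[key] = event
    return sorted(best.values(), key=lambda e: (e.donor, e.acceptor))


def detect_water_bridges(
    coords: np.ndarray,
    structure: Structure,
    site_center: np.ndarray,
    radius: float = 10.0,
    criteria: HBondCriteria = HBondCriteria(),
    table: DonorAcceptorTable | None = None,
    frame: int = 0,
) -> list[WaterBridge]:
    """Waters near the site bridging protein and DNA by hydrogen bonds.

    A bridge is one water residue whose oxygen lies within ``radius`` of
    ``site_center`` and that hydrogen-bonds (per ``criteria``, in either
    donor/acceptor direction) to at least one protein atom and at least
    one DNA atom in the same frame. One :class:`WaterBridge` is reported
    per qualifying water, carrying one representative event per side.
    """
    kinds = [classify_residue(a.res_name) for a in structure.atoms]
    if "water" not in kinds:
        warnings.warn("structure contains no water: no bridges possible")
        return []
    if table is None:
        table = assign_donors_acceptors(structure)
    coords = np.asarray(coords, dtype=float)
    site_center = np.asarray(site_center, dtype=float)

    events = detect_hbonds(coords, table, criteria=criteria, frame=frame)
    # water residue -> {"protein": event, "dna": event}
    sides: dict[tuple[str, int], dict[str, HBondEvent]] = {}
    for ev in events:
        for water_atom, partner_atom in ((ev.donor, ev.acceptor), (ev.acceptor, ev.donor)):
            wa = structure.atoms[water_atom]
            if classify_residue(wa.res_name) != "water":
                continue
            partner_kind = kinds[partner_atom]
            if partner_kind not in ("protein", "dna"):
                continue
            key = (wa.chain_id, wa.res_seq)
            sides.setdefault(key, {}).setdefault(partner_kind, ev)

    bridges: list[WaterBridge] = []
    oxygens = {
        (a.chain_id, a.res_seq): i
        for i, a in enumerate(structure.atoms)
        if classify_residue(a.res_name) == "water" and not a.is_hydrogen
    }
    for key, found in sorted(sides.items()):
        if "protein" not in found or "dna" not in found:
            continue
        o_idx = oxygens.get(key)
        if o_idx is None:
            continue
        if np.linalg.norm(coords[o_idx] - site_center) >= radius:
            continue
        bridges.append(
            WaterBridge(
                water_res=key,
                protein_event=found["protein"],
                dna_event=found["dna"],
                frame=frame,
            )
        )
    return bridges


def hbond_statistics(
    events_per_frame: list[list[HBondEvent]],
    n_frames: int,
    dt_ps: float,
    structure: Structure | None = None,
) -> tuple[list[HBondSummary], np.ndarray]:
    """Occupancy and duration statistics over a trajectory.

    Per (donor, acceptor) key: occupancy is the fraction of frames where
    the bond is present; each maximal run of consecutive frames is one
    event of duration (run length x dt_ps); ``mean_duration_ps``
    averages over events. Also returns the per-frame total bond-count
    trace used to compare systems.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if len(events_per_frame) != n_frames:
        raise ValueError("events_per_frame length must equal n_frames")

    counts = np.array([len(evts) for evts in events_per_frame], dtype=int)
    presence: dict[tuple[int, int], np.ndarray] = {}
    for f, evts in enumerate(events_per_frame):
        for ev in evts:
            key = (ev.donor, ev.acceptor)
            if key not in presence:
                presence[key] = np.zeros(n_frames, dtype=bool)
            presence[key][f] = True

    summaries: list[HBondSummary] = []
    for (d, a), mask in sorted(presence.items()):
        padded = np.concatenate(([False], mask, [False])).astype(int)
        edges = np.diff(padded)
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        run_lengths = ends - starts
        durations = run_lengths * dt_ps
        if structure is not None:
            d_label, a_label = atom_label(structure, d), atom_label(structure, a)
        else:
            d_label, a_label = f"atom{d}", f"atom{a}"
        summaries.append(
            HBondSummary(
                donor_label=d_label,
                acceptor_label=a_label,
                occupancy=float(mask.sum() / n_frames),
                mean_duration_ps=float(durations.mean()) if len(durations) else 0.0,
                n_events=int(len(durations)),
            )
        )
    return summaries, counts


def trajectory_hbonds(
    traj: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
) -> tuple[list[HBondSummary], np.ndarray]:
    """Detect bonds frame-by-frame over a trajectory and summarise them."""
    table = assign_donors_acceptors(traj.topology)
    events_per_frame = [
        detect_hbonds(traj.frames[i], table, criteria=criteria, frame=i)
        for i in range(traj.n_frames)
    ]
    return hbond_statistics(
        events_per_frame, traj.n_frames, traj.dt_ps, traj.topology
    )
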
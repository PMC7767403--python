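import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from snpbindshift import (
    Atom,
    HBondCriteria,
    HBondEvent,
    Structure,
    assign_donors_acceptors,
    build_duplex,
    detect_hbonds,
    detect_water_bridges,
    hbond_statistics,
)
from snpbindshift.synthetic_data import pair_centroid


def _water(chain, res, origin, h1=None, h2=None):
    origin = np.asarray(origin, float)
    h1 = origin + np.array([0.96, 0, 0]) if h1 is None else np.asarray(h1, float)
    h2 = origin + np.array([-0.24, 0.93, 0]) if h2 is None else np.asarray(h2, float)
    base = 1000 * ord(chain) + 10 * res
    return [
        Atom(base, "OW", "HOH", res, chain, tuple(origin), record="HETATM"),
        Atom(base + 1, "HW1", "HOH", res, chain, tuple(h1), record="HETATM"),
        Atom(base + 2, "HW2", "HOH", res, chain, tuple(h2), record="HETATM"),
    ]


class TestAssignment:
    def test_water_chemistry(self):
        s = Structure(_water("W", 1, [0, 0, 0]))
        table = assign_donors_acceptors(s)
        assert len(table.donors) == 1
        heavy, hydrogens = table.donors[0]
        assert s.atoms[heavy].name == "OW" and len(hydrogens) == 2
        assert [s.atoms[i].name for i in table.acceptors] == ["OW"]

    def test_cytosine_ring_face(self):
        s = build_duplex("G")  # pair G.C: cytosine sits on chain B
        table = assign_donors_acceptors(s)
        cyt = {
            i: a for i, a in enumerate(s.atoms) if a.chain_id == "B" and a.res_name == "DC"
        }
        donors = {s.atoms[d].name for d, _ in table.donors if d in cyt}
        acceptors = {s.atoms[a].name for a in table.acceptors if a in cyt}
        assert donors == {"N4"}
        assert {"N3", "O2"} <= acceptors

    def test_no_hydrogens_warns_and_yields_no_donors(self):
        s = build_duplex("A")
        stripped = Structure([a for a in s.atoms if not a.is_hydrogen])
        with pytest.warns(UserWarning, match="no hydrogens"):
            table = assign_donors_acceptors(stripped)
        assert table.donors == [] and len(table.acceptors) > 0

    def test_detached_hydrogen_is_a_topology_error(self):
        atoms = _water("W", 1, [0, 0, 0])
        lone = Atom(9999, "HW1", "HOH", 2, "W", (8.0, 8.0, 8.0), record="HETATM")
        with pytest.raises(ValueError, match="no heavy atom"):
            assign_donors_acceptors(Structure(atoms + [lone]))


class TestDetection:
    @pytest.mark.parametrize("base,n_bonds", [("G", 3), ("C", 3), ("A", 2), ("T", 2)])
    def test_watson_crick_counts(self, base, n_bonds):
        s = build_duplex(base)
        events = detect_hbonds(s.coordinates(), assign_donors_acceptors(s))
        assert len(events) == n_bonds

    def test_distance_criterion_is_strict(self):
        # perfect angle, donor-acceptor at 3.5 A: rejected
        atoms = _water("W", 1, [0, 0, 0], h1=[1.0, 0, 0], h2=[-0.24, 0.93, 0])
        atoms += _water("X", 2, [3.5, 0, 0], h1=[3.5, 1.0, 0], h2=[3.5, -0.24, 0.93])
        s = Structure(atoms)
        assert detect_hbonds(s.coordinates(), assign_donors_acceptors(s)) == []

    def test_angle_criterion_is_strict(self):
        # 2.8 A distance but the hydrogen 25 degrees off the D->A axis
        theta = np.radians(25.0)
        h1 = [np.cos(theta), np.sin(theta), 0]
        atoms = _water("W", 1, [0, 0, 0], h1=h1, h2=[-0.24, -0.93, 0])
        atoms += _water("X", 2, [2.8, 0, 0], h1=[2.8, 1.0, 0], h2=[2.8, -0.24, -0.93])
        s = Structure(atoms)
        assert detect_hbonds(s.coordinates(), assign_donors_acceptors(s)) == []

    def test_bonds_accepted_inside_cutoffs(self):
        atoms = _water("W", 1, [0, 0, 0], h1=[1.0, 0, 0], h2=[-0.24, 0.93, 0])
        atoms += _water("X", 2, [2.8, 0, 0], h1=[2.8, 1.0, 0], h2=[2.8, -0.24, 0.93])
        s = Structure(atoms)
        events = detect_hbonds(s.coordinates(), assign_donors_acceptors(s))
        assert len(events) == 1
        assert events[0].distance == pytest.approx(2.8)
        assert events[0].angle == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_global_rigid_transform(self, wet_complex):
        table = assign_donors_acceptors(wet_complex)
        coords = wet_complex.coordinates()
        base = detect_hbonds(coords, table)
        rot = Rotation.from_rotvec([1.0, 0.2, -0.4]).as_matrix()
        moved = coords @ rot.T + np.array([10.0, -5.0, 3.0])
        transformed = detect_hbonds(moved, table)
        assert [(e.donor, e.acceptor) for e in base] == [
            (e.donor, e.acceptor) for e in transformed
        ]

    def test_enumeration_order_does_not_matter(self, wet_complex):
        table = assign_donors_acceptors(wet_complex)
        coords = wet_complex.coordinates()
        base = detect_hbonds(coords, table.donors, table.acceptors)
        shuffled = detect_hbonds(
            coords, list(reversed(table.donors)), list(reversed(table.acceptors))
        )
        assert base == shuffled


class TestWaterBridges:
    def test_constructed_fixture_has_one_bridge(self, wet_complex, site):
        center = pair_centroid(wet_complex, site)
        bridges = detect_water_bridges(wet_complex.coordinates(), wet_complex, center)
        assert len(bridges) == 1
        assert bridges[0].protein_event != bridges[0].dna_event

    def test_radius_excludes_distant_water(self, wet_complex, site):
        coords = wet_complex.coordinates().copy()
        widx = [i for i, a in enumerate(wet_complex.atoms) if a.res_name == "HOH"]
        center = pair_centroid(wet_complex, site)
        ow = next(i for i in widx if wet_complex.atoms[i].name == "OW")
        away = (coords[ow] - center) / np.linalg.norm(coords[ow] - center)
        for i in widx:
            coords[i] = coords[i] + 12.0 * away
        assert detect_water_bridges(coords, wet_complex, center) == []

    def test_dna_only_water_is_no_bridge(self, mut_duplex, site):
        # a duplex plus water (no protein chain at all)
        o2p = next(
            a for a in mut_duplex.atoms
            if a.chain_id == "B" and a.res_seq == site and a.name == "O2P"
        )
        q = np.array(o2p.coords)
        u = np.array([q[0], q[1], 0.0])
        u /= np.linalg.norm(u)
        ow = q + 2.9 * u
        atoms = list(mut_duplex.atoms) + _water(
            "W", 1, ow, h1=ow + (q - ow) / 2.9, h2=ow + np.array([0, 0, 1.0])
        )
        s = Structure(atoms)
        center = pair_centroid(s, site)
        table = assign_donors_acceptors(s)
        dna_bonds = [
            e
            for e in detect_hbonds(s.coordinates(), table)
            if s.atoms[e.donor].res_name == "HOH" or s.atoms[e.acceptor].res_name == "HOH"
        ]
        assert dna_bonds  # the water does bond the DNA...
        assert detect_water_bridges(s.coordinates(), s, center) == []  # ...but bridges nothing

    def test_no_water_warns_and_returns_empty(self, mut_duplex, site):
        center = pair_centroid(mut_duplex, site)
        with pytest.warns(UserWarning, match="no water"):
            assert detect_water_bridges(mut_duplex.coordinates(), mut_duplex, center) == []


def _events_for_frames(frames, n_frames):
    per_frame = [[] for _ in range(n_frames)]
    for f in frames:
        per_frame[f].append(
            HBondEvent(donor=1, hydrogen=2, acceptor=3, frame=f, distance=2.8, angle=5.0)
        )
    return per_frame


class TestStatistics:
    def test_fully_occupied_bond(self):
        summaries, counts = hbond_statistics(_events_for_frames(range(10), 10), 10, 1.0)
        (s,) = summaries
        assert s.occupancy == 1.0 and s.n_events == 1
        assert s.mean_duration_ps == pytest.approx(10.0)
        assert list(counts) == [1] * 10

    def test_hand_worked_interrupted_bond(self):
        # present in frames {0,1,2,5,6} of 10 at dt=1 ps:
        # runs of length 3 and 2 -> occupancy 0.5, 2 events, mean 2.5 ps
        summaries, _ = hbond_statistics(_events_for_frames([0, 1, 2, 5, 6], 10), 10, 1.0)
        (s,) = summaries
        assert s.occupancy == pytest.approx(0.5)
        assert s.n_events == 2
        assert s.mean_duration_ps == pytest.approx(2.5)

    def test_no_events(self):
        summaries, counts = hbond_statistics([[], [], []], 3, 1.0)
        assert summaries == [] and list(counts) == [0, 0, 0]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.booleans(), min_size=1, max_size=40),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_occupancy_and_duration_bounds(self, presence, dt_ps):
        n = len(presence)
        frames = [i for i, p in enumerate(presence) if p]
        summaries, _ = hbond_statistics(_events_for_frames(frames, n), n, dt_ps)
        for s in summaries:
            assert 0.0 <= s.occupancy <= 1.0
            assert s.n_events >= 1
            assert s.mean_duration_ps >= dt_ps - 1e-12
            assert s.n_events * s.mean_duration_ps <= n * dt_ps + 1e-9
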
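import warnings

import numpy as np
import pytest

from snpbindshift import (
    TrajectoryPreset,
    assign_donors_acceptors,
    build_duplex,
    build_toy_complex,
    ddg_bind,
    detect_hbonds,
    mutate_pair,
    place_bridging_water,
    rmsd_series,
    simulate_energy_series,
    simulate_trajectory,
)
from snpbindshift.lie import MeanEnergies
from snpbindshift.synthetic_data import (
    EnergyCell,
    EnergyPreset,
    pair_centroid,
    preset,
)


class TestDuplexBuilder:
    def test_rise_between_pairs(self):
        # identical rungs: the axial centroid spacing is exactly the rise
        s = build_duplex("AA")
        axial = pair_centroid(s, 2)[2] - pair_centroid(s, 1)[2]
        assert axial == pytest.approx(3.38, abs=1e-9)
        # mixed rungs: base compositions differ, so only approximately
        mixed = build_duplex("GA")
        axial = pair_centroid(mixed, 2)[2] - pair_centroid(mixed, 1)[2]
        assert axial == pytest.approx(3.38, abs=0.05)

    def test_invalid_characters(self):
        with pytest.raises(ValueError, match="invalid"):
            build_duplex("GAX")
        with pytest.raises(ValueError, match="non-empty"):
            build_duplex("")

    def test_passes_assignment_without_warnings(self):
        s = build_duplex("ACGT")
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            table = assign_donors_acceptors(s)
        assert table.donors and table.acceptors


class TestMutation:
    def test_hbond_count_gain(self, wt_duplex, mut_duplex, site):
        def bonds(s):
            return len(detect_hbonds(s.coordinates(), assign_donors_acceptors(s)))

        assert bonds(mut_duplex) - bonds(wt_duplex) == 1  # 2 -> 3 at the site

    def test_identity_mutation_is_noiseless(self, wt_duplex, site):
        same = mutate_pair(wt_duplex, site, "AT")
        assert same.n_atoms == wt_duplex.n_atoms
        np.testing.assert_allclose(
            same.coordinates(), wt_duplex.coordinates(), atol=1e-6
        )

    def test_locality(self, wt_duplex, mut_duplex, site):
        before = {
            (a.chain_id, a.res_seq, a.name): a.coords
            for a in wt_duplex.atoms
            if a.res_seq != site
        }
        after = {
            (a.chain_id, a.res_seq, a.name): a.coords
            for a in mut_duplex.atoms
            if a.res_seq != site
        }
        assert before.keys() == after.keys()
        for key, xyz in before.items():
            assert after[key] == xyz

    def test_out_of_range_position(self, wt_duplex):
        with pytest.raises(IndexError):
            mutate_pair(wt_duplex, 99, "GC")


class TestToyComplex:
    def test_direct_protein_dna_bond(self, mut_duplex, site):
        cx = build_toy_complex(mut_duplex, site)
        events = detect_hbonds(cx.coordinates(), assign_donors_acceptors(cx))
        kinds = {
            frozenset((cx.atoms[e.donor].chain_id, cx.atoms[e.acceptor].chain_id))
            for e in events
        }
        assert frozenset(("P", "B")) in kinds or frozenset(("P", "A")) in kinds

    def test_dna_untouched(self, mut_duplex, site):
        cx = build_toy_complex(mut_duplex, site)
        dna = [a for a in cx.atoms if a.chain_id in ("A", "B")]
        assert [(a.name, a.res_seq, a.coords) for a in dna] == [
            (a.name, a.res_seq, a.coords) for a in mut_duplex.atoms
        ]

    def test_water_within_site_radius(self, wet_complex, site):
        ow = next(a for a in wet_complex.atoms if a.name == "OW")
        dist = np.linalg.norm(np.array(ow.coords) - pair_centroid(wet_complex, site))
        assert dist < 10.0

    def test_requires_protein_chain(self, mut_duplex, site):
        with pytest.raises(ValueError, match="protein"):
            place_bridging_water(mut_duplex, site)


class TestTrajectorySimulation:
    def test_zero_sigma_is_static(self, wt_duplex):
        traj = simulate_trajectory(TrajectoryPreset(wt_duplex, sigma=0.0, n_frames=5))
        for f in range(5):
            np.testing.assert_array_equal(traj.frames[f], wt_duplex.coordinates())
        series = rmsd_series(traj, wt_duplex, fit=False)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-12)

    def test_same_seed_reproduces(self, wt_duplex):
        a = simulate_trajectory(TrajectoryPreset(wt_duplex, sigma=0.4, n_frames=4, seed=5))
        b = simulate_trajectory(TrajectoryPreset(wt_duplex, sigma=0.4, n_frames=4, seed=5))
        np.testing.assert_array_equal(a.frames, b.frames)
        c = simulate_trajectory(TrajectoryPreset(wt_duplex, sigma=0.4, n_frames=4, seed=6))
        assert not np.array_equal(a.frames, c.frames)

    def test_mean_squared_rmsd_matches_closed_form(self):
        # isotropic Gaussian displacement of scale sigma per axis gives
        # E[RMSD^2] = 3 sigma^2 against the base structure without fitting
        base = build_duplex("GA")
        traj = simulate_trajectory(
            TrajectoryPreset(base, sigma=0.5, n_frames=1000, seed=12)
        )
        values = rmsd_series(traj, base, selection="heavy", fit=False).values
        assert np.mean(values**2) == pytest.approx(0.75, rel=0.05)

    def test_hydrogens_ride_their_heavy_atom(self, wt_duplex):
        traj = simulate_trajectory(TrajectoryPreset(wt_duplex, sigma=0.5, n_frames=1, seed=3))
        base = wt_duplex.coordinates()
        # pick adenine N6/H61 of pair 4: displacement must be identical
        idx = {
            a.name: i
            for i, a in enumerate(wt_duplex.atoms)
            if a.chain_id == "A" and a.res_seq == 4
        }
        d_heavy = traj.frames[0][idx["N6"]] - base[idx["N6"]]
        d_h = traj.frames[0][idx["H61"]] - base[idx["H61"]]
        np.testing.assert_allclose(d_heavy, d_h, atol=1e-12)


class TestEnergySimulation:
    def _preset(self, **kw):
        defaults = dict(
            cells={
                (v, e): EnergyCell(mean_vdw=-50.0, mean_el=-70.0, sigma_vdw=2.0, sigma_el=2.0)
                for v in ("AT", "GC")
                for e in ("Complex", "DNA")
            },
            phi=0.9,
            seed=21,
        )
        defaults.update(kw)
        return EnergyPreset(**defaults)

    def test_deterministic_constant_limit(self):
        p = self._preset(
            cells={
                (v, e): EnergyCell(mean_vdw=-5.0, mean_el=-7.0, sigma_vdw=0.0, sigma_el=0.0)
                for v in ("AT", "GC")
                for e in ("Complex", "DNA")
            },
            phi=0.0,
            n_samples=10,
        )
        s = simulate_energy_series(p, "AT", "DNA", 0)
        np.testing.assert_array_equal(s.e_vdw, -5.0)
        np.testing.assert_array_equal(s.e_el, -7.0)

    def test_stationary_mean(self):
        p = self._preset(n_samples=100_000)
        s = simulate_energy_series(p, "GC", "Complex", 0)
        n_eff = 100_000 * (1 - 0.9) / (1 + 0.9)
        tol = 3 * 2.0 / np.sqrt(n_eff)
        assert s.e_vdw.mean() == pytest.approx(-50.0, abs=tol)
        assert s.e_el.mean() == pytest.approx(-70.0, abs=tol)

    def test_lag_one_autocorrelation(self):
        p = self._preset(n_samples=10_000)
        x = simulate_energy_series(p, "AT", "Complex", 1).e_el
        xc = x - x.mean()
        rho1 = float(np.dot(xc[:-1], xc[1:]) / np.dot(xc, xc))
        assert rho1 == pytest.approx(0.9, abs=0.05)

    def test_distinct_runs_and_channels(self):
        p = self._preset(n_samples=100)
        a = simulate_energy_series(p, "AT", "DNA", 0)
        b = simulate_energy_series(p, "AT", "DNA", 1)
        assert not np.array_equal(a.e_vdw, b.e_vdw)
        assert not np.array_equal(a.e_vdw, a.e_el + 20.0)


class TestPresets:
    def test_noiseless_paper_default_means_close_the_cycle_exactly(self):
        ds = preset("paper_default", n_runs=2, n_samples=10, n_frames=1)
        cells = {
            key: MeanEnergies(
                variant=key[0],
                environment=key[1],
                mean_vdw=cell.mean_vdw,
                mean_el=cell.mean_el,
            )
            for key, cell in ds.energy_preset.cells.items()
        }
        result = ddg_bind(cells)
        assert result.ddg == pytest.approx(-0.800, abs=1e-9)
        assert result.ddg_el_component == pytest.approx(-0.700, abs=1e-9)
        assert result.ddg_vdw_component == pytest.approx(-0.100, abs=1e-9)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset("frobnicate")

    def test_null_preset_is_variant_symmetric(self):
        ds = preset("null", n_runs=2, n_samples=50, n_frames=2, seed=3)
        for env in ("Complex", "DNA"):
            a, g = ds.energies[("AT", env)][0], ds.energies[("GC", env)][0]
            np.testing.assert_array_equal(a.e_vdw, g.e_vdw)
            np.testing.assert_array_equal(a.e_el, g.e_el)
            np.testing.assert_array_equal(
                ds.trajectories[("AT", env)][1].frames,
                ds.trajectories[("GC", env)][1].frames,
            )

    def test_mutant_trajectories_are_tighter(self):
        ds = preset("paper_default", n_runs=2, n_samples=10, n_frames=8, seed=4)
        wt = ds.trajectories[("AT", "DNA")][0]
        mut = ds.trajectories[("GC", "DNA")][0]
        wt_spread = np.std(wt.frames - wt.frames.mean(axis=0), axis=0).mean()
        mut_spread = np.std(mut.frames - mut.frames.mean(axis=0), axis=0).mean()
        assert mut_spread < wt_spread
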
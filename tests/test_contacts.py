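"""Interface contact detection and frequencies."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tubudyn as td
from tubudyn.contacts import frame_contacts
from tubudyn.io import Topology


def two_chain_topology(n_a, n_b, elements=None):
    n = n_a + n_b
    chains = np.array(["A"] * n_a + ["B"] * n_b)
    resids = np.concatenate([np.arange(1, n_a + 1), np.arange(1, n_b + 1)])
    elements = np.array(["C"] * n) if elements is None else np.asarray(elements)
    return Topology(
        ids=np.arange(1, n + 1),
        names=np.array(["CA"] * n),
        elements=elements,
        resids=resids,
        resnames=np.array(["GLY"] * n),
        chain_ids=chains,
        roles={"A": "TUBA", "B": "TUBB"},
    )


def brute_force_contacts(coords, topology, group_a, group_b, cutoff):
    """O(N^2) oracle with the same strict-inequality convention."""
    heavy = topology.heavy_mask
    out = set()
    for ia in group_a:
        if not heavy[ia]:
            continue
        for ib in group_b:
            if not heavy[ib]:
                continue
            if np.linalg.norm(coords[ia] - coords[ib]) < cutoff:
                out.add(
                    (
                        (str(topology.chain_ids[ia]), int(topology.resids[ia])),
                        (str(topology.chain_ids[ib]), int(topology.resids[ib])),
                    )
                )
    return out


class TestFrameContacts:
    def test_pair_just_inside_cutoff(self):
        top = two_chain_topology(1, 1)
        coords = np.array([[0.0, 0, 0], [3.9, 0, 0]])
        pairs = frame_contacts(coords, top, np.array([0]), np.array([1]))
        assert pairs == {(("A", 1), ("B", 1))}

    def test_pair_at_exactly_cutoff_excluded(self):
        top = two_chain_topology(1, 1)
        coords = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        assert frame_contacts(coords, top, np.array([0]), np.array([1])) == set()

    def test_hydrogens_silently_ignored(self):
        top = two_chain_topology(2, 1, elements=["C", "H", "C"])
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0.1], [5.0, 0, 0]])
        # only the hydrogen is close to chain B
        pairs = frame_contacts(coords, top, np.array([0, 1]), np.array([2]))
        assert pairs == set()

    def test_empty_group_rejected(self):
        top = two_chain_topology(1, 1)
        with pytest.raises(ValueError, match="non-empty"):
            frame_contacts(np.zeros((2, 3)), top, np.array([], dtype=int), np.array([1]))

    def test_overlapping_groups_rejected(self):
        top = two_chain_topology(1, 1)
        with pytest.raises(ValueError, match="disjoint"):
            frame_contacts(np.zeros((2, 3)), top, np.array([0, 1]), np.array([1]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), cutoff=st.floats(0.5, 8.0))
    def test_kdtree_equals_brute_force_oracle(self, seed, cutoff):
        """Property: cell-list and all-pairs implementations agree exactly on
        random 50-atom frames, for any cutoff."""
        rng = np.random.default_rng(seed)
        top = two_chain_topology(25, 25)
        coords = rng.uniform(0, 15, size=(50, 3))
        ga, gb = np.arange(25), np.arange(25, 50)
        assert frame_contacts(coords, top, ga, gb, cutoff) == brute_force_contacts(
            coords, top, ga, gb, cutoff
        )

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(1)
        top = two_chain_topology(10, 10)
        coords = rng.uniform(0, 8, size=(20, 3))
        fwd = frame_contacts(coords, top, np.arange(10), np.arange(10, 20))
        rev = frame_contacts(coords, top, np.arange(10, 20), np.arange(10))
        assert fwd == {(b, a) for a, b in rev}

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        top = two_chain_topology(15, 15)
        coords = rng.uniform(0, 10, size=(30, 3))
        ga, gb = np.arange(15), np.arange(15, 30)
        small = frame_contacts(coords, top, ga, gb, 3.0)
        large = frame_contacts(coords, top, ga, gb, 6.0)
        assert small <= large


class TestContactFrequency:
    def test_static_structure_single_pair_frequency_one(self, quiet_dimer, selection):
        traj, _ = quiet_dimer
        static = dataclasses.replace(traj, coords=np.repeat(traj.coords[:1], 10, axis=0))
        table = td.contact_frequency(static, selection)
        # every observed pair is present in every frame
        np.testing.assert_allclose(table.per_pair["frequency"], 1.0)
        np.testing.assert_allclose(table.per_residue["frequency"], 1.0)

    def test_counting_three_of_ten_frames(self, quiet_dimer, selection):
        traj, _ = quiet_dimer
        frames = np.repeat(traj.coords[:1], 10, axis=0).copy()
        # move the whole of Gln245 out of reach except in frames 0..2
        top = traj.topology
        res245 = (top.chain_ids == "B") & (top.resids == 245)
        frames[3:][:, res245] += np.array([0.0, 30.0, 0.0])
        moved = dataclasses.replace(traj, coords=frames)
        table = td.contact_frequency(moved, selection)
        pair = table.per_pair
        row = pair[(pair.resid_a == 11) & (pair.resid_b == 245)]
        assert row["frequency"].iloc[0] == pytest.approx(0.30)

    def test_two_state_occupancy_recovered(self, small_dimer, selection):
        """The contact present only in loop state A appears with exactly the
        realised state-A occupancy (cross-module ground truth)."""
        traj, manifest = small_dimer
        table = td.contact_frequency(traj, selection)
        pair = table.per_pair
        row = pair[(pair.resid_a == 11) & (pair.resid_b == 245)]
        assert row["frequency"].iloc[0] == pytest.approx(
            manifest["loop_occupancy_a_realised"], abs=0.02
        )

    def test_pooled_equals_frame_weighted_mean_of_runs(self, selection):
        p1 = td.DimerParams(n_frames=60, seed=31, run_id="r1")
        p2 = td.DimerParams(n_frames=140, seed=32, run_id="r2")
        t1, _ = td.simulate_dimer(p1)
        t2, _ = td.simulate_dimer(p2)
        table = td.contact_frequency([t1, t2], selection)
        df = table.per_residue
        recomputed = (df["freq_r1"] * 60 + df["freq_r2"] * 140) / 200
        np.testing.assert_allclose(df["frequency"], recomputed, atol=1e-12)

    def test_inconsistent_topologies_rejected(self, quiet_dimer, selection):
        traj, _ = quiet_dimer
        other, _ = td.simulate_dimer(td.DimerParams(n_frames=5, n_residues_b=400, seed=1))
        with pytest.raises(ValueError, match="topolog"):
            td.contact_frequency([traj, other], selection)


class TestContactCountDistribution:
    def test_static_frames_degenerate_histogram(self, quiet_dimer, selection):
        traj, _ = quiet_dimer
        static = dataclasses.replace(traj, coords=np.repeat(traj.coords[:1], 8, axis=0))
        dist = td.contact_count_distribution(static, selection)
        assert len(dist.histogram) == 1
        assert dist.histogram["fraction"].iloc[0] == pytest.approx(1.0)

    def test_histogram_mass_equals_frame_count(self, small_dimer, selection):
        traj, _ = small_dimer
        dist = td.contact_count_distribution(traj, selection)
        assert dist.histogram["fraction"].sum() == pytest.approx(1.0)
        assert len(dist.counts) == traj.n_frames

    def test_programmed_interface_size_orders_the_means(self, selection):
        big, _ = td.simulate_dimer(td.DimerParams(n_frames=80, n_interface_pairs=14, seed=33))
        small, _ = td.simulate_dimer(td.DimerParams(n_frames=80, n_interface_pairs=6, seed=34))
        d_big = td.contact_count_distribution(big, selection)
        d_small = td.contact_count_distribution(small, selection)
        assert d_big.mean_count > d_small.mean_count

    def test_separated_domains_have_zero_contacts(self, quiet_dimer, selection):
        traj, _ = quiet_dimer
        coords = traj.coords[:5].copy()
        is_b = traj.topology.chain_ids == "B"
        coords[:, is_b] += np.array([0.0, 0.0, 100.0])
        import warnings

        apart = dataclasses.replace(traj, coords=coords)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # the jump triggers the PBC warning
            dist = td.contact_count_distribution(apart, selection)
        assert (dist.counts["n_contacts"] == 0).all()

    def test_pbc_jump_warns(self, quiet_dimer, selection):
        traj, _ = quiet_dimer
        coords = traj.coords[:4].copy()
        is_b = traj.topology.chain_ids == "B"
        coords[2:, is_b] += np.array([0.0, 0.0, 60.0])
        jumpy = dataclasses.replace(traj, coords=coords)
        with pytest.warns(UserWarning, match="PBC"):
            td.contact_count_distribution(jumpy, selection)


class TestLigandContacts:
    def test_always_bound_residue_frequency_one(self, quiet_dimer, selection):
        traj, _ = quiet_dimer
        table = td.ligand_contact_frequency(traj, "GTP")
        df = table.per_residue
        row = df[(df.role == "TUBA") & (df.resid == 11)]
        assert row["frequency"].iloc[0] == pytest.approx(1.0)

    def test_absent_ligand_rejected(self, selection):
        traj, _ = td.simulate_dimer(td.DimerParams(n_frames=5, include_gtp=False, seed=2))
        with pytest.raises(ValueError, match="GTP"):
            td.ligand_contact_frequency(traj, "GTP")

    def test_out_of_reach_ligand_empty_table(self, quiet_dimer):
        traj, _ = quiet_dimer
        coords = traj.coords[:5].copy()
        lig = traj.topology.resnames == "GTP"
        coords[:, lig] += 500.0
        far = dataclasses.replace(traj, coords=coords)
        table = td.ligand_contact_frequency(far, "GTP")
        assert len(table.per_residue) == 0

    def test_programmed_partial_occupancy(self, quiet_dimer):
        """A residue entering the cutoff in a programmed 40% of frames gets
        frequency 0.40 exactly (deterministic construction)."""
        traj, _ = quiet_dimer
        frames = np.repeat(traj.coords[:1], 10, axis=0).copy()
        lig = traj.topology.resnames == "GTP"
        frames[4:, lig] += np.array([0.0, 50.0, 0.0])  # bound in 4 of 10 frames
        moved = dataclasses.replace(traj, coords=frames)
        table = td.ligand_contact_frequency(moved, "GTP")
        df = table.per_residue
        row = df[(df.role == "TUBA") & (df.resid == 11)]
        assert row["frequency"].iloc[0] == pytest.approx(0.40)
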
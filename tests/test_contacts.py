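"""Surface-contact geometry and contact-fraction aggregation."""

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from pepsurf import (
    ContactProfile,
    InputError,
    ResidueReference,
    Trajectory,
    compute_contact_fractions,
    default_reference_table,
    partition_atoms,
    residue_surface_distance,
    topmost_gold_z,
)
from pepsurf.contacts import load_reference_table, save_reference_table
from pepsurf.errors import ConfigurationError, TopologyError
from pepsurf.synthetic import ContactSpec, gen_contact_trajectory

from conftest import make_slab_atoms

from pepsurf import Atom, Frame


class TestTopmostGoldZ:
    def test_three_layers_returns_top_layer_mean(self, simple_system):
        traj = simple_system([9.2])
        slab, _ = partition_atoms(traj)
        assert topmost_gold_z(traj.frames[0], slab, 0.5) == pytest.approx(4.70)

    def test_single_atom(self):
        atoms = make_slab_atoms(n_per_layer=1, n_layers=1)
        frame = Frame(coordinates=np.array([[0.0, 0.0, 7.0]]), box=(10, 10, 20))
        assert topmost_gold_z(frame, {0}, 0.8) == pytest.approx(7.0)

    def test_empty_slab_rejected(self, simple_system):
        with pytest.raises(InputError):
            topmost_gold_z(simple_system([9.2]).frames[0], set(), 0.8)

    def test_jittered_layer_matches_brute_force(self, rng):
        """Thermally jittered top layer: mean over exactly the top-band atoms."""
        z = np.concatenate([
            rng.normal(0.0, 0.05, 8),
            rng.normal(2.35, 0.05, 8),
            rng.normal(4.70, 0.05, 8),
        ])
        coords = np.column_stack([np.arange(24, dtype=float), np.zeros(24), z])
        frame = Frame(coordinates=coords, box=(30, 30, 30))
        tol = 0.8
        got = topmost_gold_z(frame, set(range(24)), tol)
        expected = np.mean([v for v in z if v >= max(z) - tol])  # filter-then-average
        assert got == pytest.approx(expected)


class TestResidueSurfaceDistance:
    def test_vertical_subtraction(self, simple_system):
        traj = simple_system([9.2])
        slab, residues = partition_atoms(traj)
        ref = ResidueReference("MET", ("SD",), 4.5)
        d = residue_surface_distance(traj.frames[0], residues[0], ref,
                                     top_z=4.70, traj=traj)
        assert d == pytest.approx(4.50)

    def test_centroid_site(self):
        atoms = make_slab_atoms(n_per_layer=1, n_layers=1)
        atoms += [
            Atom(index=1, name="CA", element="C", residue_index=1, residue_name="X2"),
            Atom(index=2, name="CA2", element="C", residue_index=1, residue_name="X2"),
        ]
        coords = np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 6.0], [0.0, 0.0, 8.0]])
        traj = Trajectory(atoms=atoms,
                          frames=[Frame(coordinates=coords, box=(10, 10, 20))])
        _, residues = partition_atoms(traj)
        ref = ResidueReference("X2", ("CA", "CA2"), 4.5)
        d = residue_surface_distance(traj.frames[0], residues[0], ref,
                                     top_z=5.0, traj=traj)
        assert d == pytest.approx(2.0)

    def test_random_configurations_match_brute_force(self, rng):
        """Distance equals recomputation straight from raw coordinates."""
        for _ in range(25):
            sd_z = rng.uniform(3.0, 15.0)
            atoms = make_slab_atoms()
            n = len(atoms)
            atoms.append(Atom(index=n, name="SD", element="S",
                              residue_index=1, residue_name="MET"))
            slab_z = rng.uniform(0, 4.7, size=n)
            coords = np.column_stack([
                np.arange(n + 1, dtype=float),
                np.zeros(n + 1),
                np.append(slab_z, sd_z),
            ])
            traj = Trajectory(atoms=atoms,
                              frames=[Frame(coordinates=coords, box=(30, 30, 40))])
            slab, residues = partition_atoms(traj)
            tol = 0.8
            top = topmost_gold_z(traj.frames[0], slab, tol)
            ref = ResidueReference("MET", ("SD",), 4.5)
            d = residue_surface_distance(traj.frames[0], residues[0], ref, top,
                                         traj=traj)
            brute_top = np.mean(slab_z[slab_z >= slab_z.max() - tol])
            assert d == pytest.approx(sd_z - brute_top)

    def test_missing_site_names_residue(self, simple_system):
        traj = simple_system([9.2])
        _, residues = partition_atoms(traj)
        ref = ResidueReference("MET", ("NOPE",), 4.5)
        with pytest.raises(TopologyError, match="MET1.*NOPE"):
            residue_surface_distance(traj.frames[0], residues[0], ref, 4.7,
                                     traj=traj)


class TestContactFractions:
    def test_boundary_is_inclusive(self, simple_system):
        """A residue sitting exactly at the cut-off distance counts as contact."""
        traj = simple_system([4.70 + 4.5] * 3)
        profile = compute_contact_fractions(traj)
        assert profile.fractions[0] == 1.0

    def test_counting(self, simple_system):
        # 4 of 10 frames within the 4.5 A cut-off of the z=4.70 top layer
        zs = [4.70 + (2.0 if i < 4 else 9.0) for i in range(10)]
        profile = compute_contact_fractions(simple_system(zs))
        assert profile.fractions[0] == pytest.approx(0.4)
        assert profile.n_frames == 10

    def test_negative_distance_counts_as_contact(self, simple_system):
        profile = compute_contact_fractions(simple_system([3.0]))  # below top layer
        assert profile.fractions[0] == 1.0

    def test_planted_pattern_recovered_exactly(self):
        spec = ContactSpec(contact_probabilities=(0.8, 0.3), n_frames=500,
                           correlation=0.4, seed=11)
        traj, truth = gen_contact_trajectory(spec)
        profile = compute_contact_fractions(traj)
        assert np.array_equal(profile.per_frame_contacts, truth)
        assert np.allclose(profile.fractions, truth.mean(axis=0))

    def test_missing_residue_type_listed(self, simple_system):
        traj = simple_system([9.2])
        table = [ResidueReference("ALA", ("CB",), 4.5)]
        with pytest.raises(ConfigurationError, match="MET"):
            compute_contact_fractions(traj, table)

    def test_concatenation_is_frame_weighted_mean(self, simple_system):
        za = [4.70 + 2.0] * 4          # all contact
        zb = [4.70 + 9.0] * 8          # none
        fa = compute_contact_fractions(simple_system(za)).fractions
        fb = compute_contact_fractions(simple_system(zb)).fractions
        fab = compute_contact_fractions(simple_system(za + zb)).fractions
        assert np.allclose(fab, (4 * fa + 8 * fb) / 12)

    @settings(max_examples=30, deadline=None, derandomize=True,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    @given(cutoffs=st.lists(st.floats(0.5, 12.0), min_size=2, max_size=6))
    def test_fraction_monotone_in_cutoff(self, simple_system, cutoffs):
        """For fixed geometry, f_i never decreases as the cut-off grows."""
        zs = [4.70 + d for d in (1.0, 3.0, 5.0, 7.0, 9.0, 11.0)]
        traj = simple_system(zs)
        fractions = []
        for c in sorted(cutoffs):
            table = [ResidueReference("MET", ("SD",), c)]
            fractions.append(compute_contact_fractions(traj, table).fractions[0])
        assert all(a <= b + 1e-12 for a, b in zip(fractions, fractions[1:]))

    def test_min3d_agrees_with_vertical_above_an_atom(self, simple_system):
        """Site straight above a top-layer atom: 3-D distance == z-offset."""
        traj = simple_system([4.70 + 3.0])
        # place SD exactly above slab atom at x=1.0 (it already is, y=0)
        v = compute_contact_fractions(traj, method="vertical").fractions
        m = compute_contact_fractions(traj, method="min3d").fractions
        assert np.array_equal(v, m)


class TestReferenceTable:
    def test_default_covers_standard_and_modified_residues(self):
        names = {r.residue_name for r in default_reference_table()}
        assert {"MET", "CYS", "MOX", "CTB", "COX", "THR", "GLY"} <= names
        assert all(r.cutoff > 0 for r in default_reference_table())

    def test_tsv_round_trip(self, tmp_path):
        table = default_reference_table()
        path = tmp_path / "refs.tsv"
        save_reference_table(table, path)
        back = load_reference_table(path)
        assert back == table

    def test_yaml_load(self, tmp_path):
        path = tmp_path / "refs.yaml"
        path.write_text(
            "residues:\n"
            "  - {residue_name: MET, site_atoms: SD, cutoff_angstrom: 4.5}\n"
            "  - {residue_name: ASP, site_atoms: 'OD1, OD2', cutoff_angstrom: 3.9}\n"
        )
        table = load_reference_table(path)
        assert table[1].site_atoms == ("OD1", "OD2")
        assert table[1].cutoff == 3.9

    def test_profile_tsv_round_trip(self, simple_system, tmp_path):
        profile = compute_contact_fractions(simple_system([6.0, 20.0]))
        path = tmp_path / "contacts.tsv"
        profile.to_tsv(path)
        back = ContactProfile.from_tsv(path)
        assert np.allclose(back.fractions, profile.fractions)
        assert back.n_frames == 2
        assert back.labels == profile.labels
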
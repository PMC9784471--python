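"""Contact engine: classification rules, oracle equality, properties."""

import numpy as np
import pytest

from conftest import (brute_force_contacts, contact_keys,
                      expected_planted_keys, random_fixture_spec)
from taucore.contacts import (ContactParams, aggregate_residue_pairs,
                              find_contacts, neighbors_of, neighbour_ids,
                              pairs_to_frame)
from taucore.structure import Protomer, select_protomer
from taucore.synthetic import (ContactFixtureSpec, PlantedPair,
                               make_contact_fixture)


def _protomer(spec, seed=0):
    return select_protomer(make_contact_fixture(spec, seed=seed))


def _spec(pairs):
    residues = (("A", 10, "TYR"), ("A", 14, "HIS"),
                ("A", 20, "VAL"), ("A", 25, "LEU"))
    return ContactFixtureSpec(residues=residues, planted_pairs=tuple(pairs))


class TestClassificationRules:
    def test_polar_pair_inside_hbond_cutoff(self):
        protomer = _protomer(_spec([
            PlantedPair(atom_a=(10, "OH"), atom_b=(14, "NE2"),
                        distance=3.2, intended_type="hbond")]))
        contacts = find_contacts(protomer)
        assert len(contacts) == 1
        assert contacts[0].bond_type == "hbond"
        assert contacts[0].distance == pytest.approx(3.2, abs=1e-6)

    def test_polar_pair_beyond_hbond_is_nothing(self):
        """A donor/acceptor pair at 3.4 A is not an hbond and, being polar
        atoms, not hydrophobic either; the 4.9 A apolar pair is."""
        protomer = _protomer(_spec([
            PlantedPair(atom_a=(10, "OH"), atom_b=(14, "NE2"),
                        distance=3.4, intended_type="hbond"),
            PlantedPair(atom_a=(20, "CG1"), atom_b=(25, "CD1"),
                        distance=4.9, intended_type="hydrophobic")]))
        contacts = find_contacts(protomer)
        assert [c.bond_type for c in contacts] == ["hydrophobic"]

    def test_apolar_pair_beyond_cutoff_is_nothing(self):
        protomer = _protomer(_spec([
            PlantedPair(atom_a=(20, "CG1"), atom_b=(25, "CD1"),
                        distance=5.1, intended_type="none")]))
        assert find_contacts(protomer) == []

    def test_tie_at_cutoff_included(self):
        """Both cutoffs are inclusive maxima."""
        protomer = _protomer(_spec([
            PlantedPair(atom_a=(10, "OH"), atom_b=(14, "NE2"),
                        distance=3.3, intended_type="hbond"),
            PlantedPair(atom_a=(20, "CG1"), atom_b=(25, "CD1"),
                        distance=5.0, intended_type="hydrophobic")]))
        assert sorted(c.bond_type for c in find_contacts(protomer)) == \
            ["hbond", "hydrophobic"]

    def test_min_seq_separation_excludes_near_pairs(self):
        spec = ContactFixtureSpec(
            residues=(("A", 10, "TYR"), ("A", 12, "HIS")),
            planted_pairs=(PlantedPair(atom_a=(10, "OH"), atom_b=(12, "NE2"),
                                       distance=3.0, intended_type="hbond"),))
        protomer = _protomer(spec)
        assert find_contacts(protomer, ContactParams()) == []
        loose = ContactParams(min_seq_separation=2)
        assert len(find_contacts(protomer, loose)) == 1

    def test_backbone_backbone_excluded_by_default(self):
        spec = ContactFixtureSpec(
            residues=(("A", 10, "GLY"), ("A", 20, "GLY")),
            planted_pairs=(PlantedPair(atom_a=(10, "N"), atom_b=(20, "O"),
                                       distance=2.9, intended_type="hbond"),))
        protomer = _protomer(spec)
        assert find_contacts(protomer) == []
        on = ContactParams(include_backbone_backbone=True)
        assert [c.bond_type for c in find_contacts(protomer, on)] == ["hbond"]

    def test_unknown_residue_raises_unless_ignored(self, simple_structure):
        protomer = select_protomer(simple_structure)
        weird = Protomer(
            source_id=protomer.source_id, chain_id=protomer.chain_id,
            seq_ids=protomer.seq_ids,
            res_names=np.array(["XYZ"] * protomer.n_atoms, dtype=object),
            atom_names=protomer.atom_names, coords=protomer.coords,
            is_donor=protomer.is_donor, is_acceptor=protomer.is_acceptor,
            is_apolar=protomer.is_apolar, is_backbone=protomer.is_backbone)
        with pytest.raises(ValueError, match="typing template"):
            find_contacts(weird)
        find_contacts(weird, ignore_unknown_residues=True)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ContactParams(hbond_max=6.0, hydrophobic_max=5.0)
        with pytest.raises(ValueError):
            ContactParams(min_seq_separation=-1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(12))
    def test_engine_equals_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        spec = random_fixture_spec(rng, n_residues=int(rng.integers(10, 80)))
        protomer = _protomer(spec, seed=trial)
        assert contact_keys(find_contacts(protomer)) == \
            brute_force_contacts(protomer)

    def test_engine_equals_planted_truth(self):
        rng = np.random.default_rng(7)
        for trial in range(8):
            spec = random_fixture_spec(rng, n_residues=40)
            protomer = _protomer(spec, seed=trial)
            assert contact_keys(find_contacts(protomer)) == \
                expected_planted_keys(spec)

    def test_nondefault_params_equal_oracle(self):
        rng = np.random.default_rng(55)
        spec = random_fixture_spec(rng, 50)
        protomer = _protomer(spec, seed=3)
        params = ContactParams(hbond_max=3.0, hydrophobic_max=4.5,
                               min_seq_separation=0,
                               include_backbone_backbone=True)
        assert contact_keys(find_contacts(protomer, params)) == \
            brute_force_contacts(protomer, 3.0, 4.5, 0, True)


class TestProperties:
    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(200)
        for trial in range(6):
            protomer = _protomer(random_fixture_spec(rng, 40), seed=trial)
            tight = contact_keys(find_contacts(
                protomer, ContactParams(hbond_max=3.0, hydrophobic_max=4.5)))
            wide = contact_keys(find_contacts(protomer, ContactParams()))
            assert tight <= wide

    def test_loosest_params_superset(self):
        rng = np.random.default_rng(300)
        protomer = _protomer(random_fixture_spec(rng, 40), seed=9)
        loosest = contact_keys(find_contacts(protomer, ContactParams(
            min_seq_separation=0, include_backbone_backbone=True)))
        stricter = contact_keys(find_contacts(protomer, ContactParams(
            min_seq_separation=5)))
        assert stricter < loosest or stricter == loosest

    def test_atom_order_permutation_invariance(self):
        rng = np.random.default_rng(400)
        protomer = _protomer(random_fixture_spec(rng, 30), seed=4)
        perm = rng.permutation(protomer.n_atoms)
        shuffled = Protomer(
            source_id=protomer.source_id, chain_id=protomer.chain_id,
            seq_ids=protomer.seq_ids[perm],
            res_names=protomer.res_names[perm],
            atom_names=protomer.atom_names[perm],
            coords=protomer.coords[perm],
            is_donor=protomer.is_donor[perm],
            is_acceptor=protomer.is_acceptor[perm],
            is_apolar=protomer.is_apolar[perm],
            is_backbone=protomer.is_backbone[perm])
        assert contact_keys(find_contacts(shuffled)) == \
            contact_keys(find_contacts(protomer))


class TestAggregation:
    def test_empty_contacts_empty_table(self):
        assert aggregate_residue_pairs([]) == []

    def test_counts_and_min_distance(self):
        spec = ContactFixtureSpec(
            residues=(("A", 310, "TYR"), ("A", 337, "VAL")),
            planted_pairs=(
                PlantedPair(atom_a=(310, "CD1"), atom_b=(337, "CG1"),
                            distance=4.5, intended_type="hydrophobic"),
                PlantedPair(atom_a=(310, "CE1"), atom_b=(337, "CG2"),
                            distance=4.1, intended_type="hydrophobic"),
                PlantedPair(atom_a=(310, "OH"), atom_b=(337, "N"),
                            distance=3.0, intended_type="hbond"),
            ))
        pairs = aggregate_residue_pairs(find_contacts(_protomer(spec)))
        assert len(pairs) == 1
        row = pairs[0]
        assert (row.n_hbond, row.n_hydrophobic) == (1, 2)
        assert row.min_distance == pytest.approx(3.0, abs=1e-6)
        assert row.dominant_type == "hbond"  # one hbond dominates
        assert row.seq_ids == (310, 337)

    def test_frame_column_order(self):
        frame = pairs_to_frame([])
        assert list(frame.columns) == [
            "seq_id_a", "res_a", "seq_id_b", "res_b", "n_hbond",
            "n_hydrophobic", "min_distance", "dominant_type"]


class TestNeighbors:
    def _pairs(self):
        spec = ContactFixtureSpec(
            residues=(("A", 310, "TYR"), ("A", 374, "HIS"),
                      ("A", 376, "LEU"), ("A", 400, "VAL")),
            planted_pairs=(
                PlantedPair(atom_a=(310, "OH"), atom_b=(374, "NE2"),
                            distance=3.0, intended_type="hbond"),
                PlantedPair(atom_a=(310, "CD1"), atom_b=(376, "CD1"),
                            distance=4.2, intended_type="hydrophobic"),
            ))
        return aggregate_residue_pairs(find_contacts(_protomer(spec)))

    def test_neighbours_of_motif_residue(self):
        pairs = self._pairs()
        assert neighbour_ids(pairs, {310}) == {374, 376}
        assert len(neighbors_of(pairs, {310})) == 2

    def test_disjoint_query_empty(self):
        assert neighbors_of(self._pairs(), {999}) == []
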
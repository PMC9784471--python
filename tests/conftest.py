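"""Shared fixtures: an independent all-pairs contact oracle and random
fixture-spec generation used across the contact-engine tests."""

from __future__ import annotations

import numpy as np
import pytest

from taucore.constructs import load_domain_map, load_template
from taucore.structure import ModeledSequence, Protomer, atom_flags
from taucore.synthetic import (RESIDUE_ATOMS, ContactFixtureSpec, PlantedPair,
                               make_contact_fixture)

ContactKey = tuple[int, str, int, str, str]  # seq_a, atom_a, seq_b, atom_b, type


def brute_force_contacts(protomer: Protomer, hbond_max: float = 3.3,
                         hydrophobic_max: float = 5.0,
                         min_seq_separation: int = 3,
                         include_backbone_backbone: bool = False
                         ) -> set[ContactKey]:
    """Exhaustive all-pairs reference, independent of the k-d tree engine.

    Applies the same contact rules over the full dense distance matrix and
    returns canonical keys for set comparison.
    """
    x = protomer.coords
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    seq = protomer.seq_ids
    admissible = np.triu(np.ones_like(d, dtype=bool), k=1)
    admissible &= np.abs(seq[:, None] - seq[None, :]) >= min_seq_separation
    if not include_backbone_backbone:
        admissible &= ~(protomer.is_backbone[:, None]
                        & protomer.is_backbone[None, :])
    polar = (protomer.is_donor[:, None] & protomer.is_acceptor[None, :]) | \
            (protomer.is_acceptor[:, None] & protomer.is_donor[None, :])
    hbond = admissible & polar & (d <= hbond_max)
    hydro = admissible & (protomer.is_apolar[:, None]
                          & protomer.is_apolar[None, :]) \
        & (d <= hydrophobic_max)

    out: set[ContactKey] = set()
    for kind, mask in (("hbond", hbond), ("hydrophobic", hydro)):
        for i, j in np.argwhere(mask):
            a = (int(seq[i]), str(protomer.atom_names[i]))
            b = (int(seq[j]), str(protomer.atom_names[j]))
            if a > b:
                a, b = b, a
            out.add((a[0], a[1], b[0], b[1], kind))
    return out


def contact_keys(contacts) -> set[ContactKey]:
    return {(c.atom_a[1], c.atom_a[3], c.atom_b[1], c.atom_b[3], c.bond_type)
            for c in contacts}


_RES_POOL = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
             "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
             "TYR", "VAL"]


def _pick_atoms(rng, res_a: str, res_b: str, kind: str):
    """A planted-pair atom choice valid for the requested contact type."""
    def sidechain(res):
        return [a for a in RESIDUE_ATOMS[res] if a not in
                ("N", "CA", "C", "O", "OXT")]

    if kind == "hydrophobic":
        apo_a = [a for a in RESIDUE_ATOMS[res_a] if atom_flags(res_a, a)[2]]
        apo_b = [a for a in RESIDUE_ATOMS[res_b] if atom_flags(res_b, a)[2]]
        if not apo_a or not apo_b:
            return None
        return rng.choice(apo_a), rng.choice(apo_b)
    # polar: need donor/acceptor with at least one sidechain atom so the
    # backbone-backbone exclusion cannot swallow the pair
    don_a = [a for a in sidechain(res_a) if atom_flags(res_a, a)[0]]
    if don_a:
        acc_b = [a for a in RESIDUE_ATOMS[res_b] if atom_flags(res_b, a)[1]]
        if acc_b:
            return rng.choice(don_a), rng.choice(acc_b)
    acc_a = [a for a in sidechain(res_a) if atom_flags(res_a, a)[1]]
    don_b = [a for a in RESIDUE_ATOMS[res_b] if atom_flags(res_b, a)[0]]
    if acc_a and don_b:
        return rng.choice(acc_a), rng.choice(don_b)
    return None


def random_fixture_spec(rng: np.random.Generator,
                        n_residues: int) -> ContactFixtureSpec:
    """Random residues with random planted pairs of every intended type."""
    seq_ids = np.cumsum(rng.integers(1, 4, size=n_residues)) + 1
    residues = tuple(("A", int(s), str(rng.choice(_RES_POOL)))
                     for s in seq_ids)
    by_id = {s: r for _, s, r in residues}
    ids = [s for _, s, _ in residues]
    used: set[tuple[int, str]] = set()
    pairs: list[PlantedPair] = []
    n_pairs = int(rng.integers(0, max(2, n_residues // 4)))
    for _ in range(n_pairs):
        ia, ib = rng.choice(len(ids), size=2, replace=False)
        sa, sb = ids[ia], ids[ib]
        if abs(sa - sb) < 3:
            continue
        kind = str(rng.choice(["hbond", "hbond_far", "hydrophobic", "none"]))
        want = "hbond" if kind.startswith("hbond") else kind
        if want == "none":
            # decoy: any template atoms, strictly beyond both cutoffs
            aa = str(rng.choice(RESIDUE_ATOMS[by_id[sa]]))
            ab = str(rng.choice(RESIDUE_ATOMS[by_id[sb]]))
            dist = float(rng.uniform(5.5, 7.5))
        else:
            picked = _pick_atoms(rng, by_id[sa], by_id[sb], want)
            if picked is None:
                continue
            aa, ab = str(picked[0]), str(picked[1])
            if kind == "hbond":
                dist = float(rng.uniform(2.6, 3.3))
            elif kind == "hbond_far":
                dist = float(rng.uniform(3.35, 4.9))  # polar but beyond 3.3
            else:
                dist = float(rng.uniform(3.6, 5.0))
        if ((sa, aa) in used or (sb, ab) in used or (sa, aa) == (sb, ab)):
            continue
        used.update({(sa, aa), (sb, ab)})
        pairs.append(PlantedPair(atom_a=(sa, aa), atom_b=(sb, ab),
                                 distance=dist, intended_type=want))
    return ContactFixtureSpec(residues=residues, planted_pairs=tuple(pairs))


def expected_planted_keys(spec: ContactFixtureSpec) -> set[ContactKey]:
    """The contacts a correct engine must report for a generated fixture:
    exactly the planted pairs within their type cutoff."""
    out: set[ContactKey] = set()
    for p in spec.planted_pairs:
        if p.intended_type == "hbond" and p.distance <= 3.3:
            kind = "hbond"
        elif p.intended_type == "hydrophobic" and p.distance <= 5.0:
            kind = "hydrophobic"
        else:
            continue
        a, b = sorted((p.atom_a, p.atom_b))
        out.add((a[0], a[1], b[0], b[1], kind))
    return out


@pytest.fixture(scope="session")
def template() -> str:
    return load_template()


@pytest.fixture(scope="session")
def domain_map():
    return load_domain_map()


@pytest.fixture(scope="session")
def full_modeled_sequence(template) -> ModeledSequence:
    return ModeledSequence(sequence=template,
                           seq_ids=list(range(1, len(template) + 1)))


@pytest.fixture
def simple_spec() -> ContactFixtureSpec:
    """One polar pair inside 3.3 A and one apolar pair inside 5.0 A."""
    return ContactFixtureSpec(
        residues=(("A", 10, "TYR"), ("A", 14, "HIS"),
                  ("A", 20, "VAL"), ("A", 25, "LEU")),
        planted_pairs=(
            PlantedPair(atom_a=(10, "OH"), atom_b=(14, "NE2"),
                        distance=3.2, intended_type="hbond"),
            PlantedPair(atom_a=(20, "CG1"), atom_b=(25, "CD1"),
                        distance=4.6, intended_type="hydrophobic"),
        ))


@pytest.fixture
def simple_structure(simple_spec):
    return make_contact_fixture(simple_spec, seed=7)
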
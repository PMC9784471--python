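"""Synthetic stand-in protomers for the eight tauopathy protofilament folds.

The published protofilament folds (AD 5O3L, CTE 6NWP, PiD 6GX5, CBD 6TJO,
AGD 7P6D, PSP 7P65, GGT 7P66, GPT 7P6A) can be analysed directly from their
depositions via `structure.read_structure` when the files are available
(e.g. fetched with ``taucore classify --fetch``).  For fully offline work
this module builds *synthetic stand-ins* from a packaged profile table that
records, per fold, (a) the modeled author-residue range(s) of the ordered
core on 2N4R numbering and (b) the reported sidechain neighbourhood of the
hexamer suffix residues as planted atom pairs.

A stand-in reproduces exactly the properties this package analyses — which
residues are ordered (hence which nucleation cores are present) and which
residue pairs interact at which distance class — while its overall geometry
is schematic.  Everything downstream (motif scan, strain classification,
truncation loss, core ranking) treats a stand-in identically to a parsed
deposition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import gemmi

from .constructs import load_template
from .structure import ONE_TO_THREE, Protomer, select_protomer
from .synthetic import ContactFixtureSpec, PlantedPair, make_contact_fixture

__all__ = ["FoldProfile", "load_fold_profiles", "fold_fixture_spec",
           "build_fold_structure", "build_fold_protomer",
           "build_all_fold_protomers", "SINGLE_CORE_FOLDS", "DUAL_CORE_FOLDS"]

SINGLE_CORE_FOLDS = ("AD", "CTE", "PiD")
DUAL_CORE_FOLDS = ("CBD", "AGD", "PSP", "GGT", "GPT")


@dataclass(frozen=True)
class FoldProfile:
    name: str
    pdb_id: str
    disease: str
    modeled_ranges: tuple[tuple[int, int], ...]
    planted_contacts: tuple[dict, ...]

    def modeled_seq_ids(self) -> list[int]:
        ids: list[int] = []
        for start, end in self.modeled_ranges:
            ids.extend(range(start, end + 1))
        return ids

    def expected_pairs(self, motif_name: str) -> set[tuple[int, int]]:
        """Planted residue pairs attributed to one core, canonical order."""
        out = set()
        for c in self.planted_contacts:
            if c["motif"] == motif_name:
                a, b = sorted((c["res_a"], c["res_b"]))
                out.add((a, b))
        return out


def load_fold_profiles() -> dict[str, FoldProfile]:
    raw = json.loads(resources.files("taucore.data").joinpath(
        "fold_profiles.json").read_text())
    profiles = {}
    for name, entry in raw.items():
        if name.startswith("_"):
            continue
        profiles[name] = FoldProfile(
            name=name, pdb_id=entry["pdb_id"], disease=entry["disease"],
            modeled_ranges=tuple(tuple(r) for r in entry["modeled_ranges"]),
            planted_contacts=tuple(entry["planted_contacts"]))
    return profiles


def fold_fixture_spec(profile: FoldProfile,
                      template: str | None = None,
                      decoy_min_distance: float = 8.0) -> ContactFixtureSpec:
    """Fixture spec realising one fold profile on the canonical sequence."""
    template = template or load_template()
    residues = tuple(
        ("A", sid, ONE_TO_THREE[template[sid - 1]])
        for sid in profile.modeled_seq_ids())
    pairs = tuple(
        PlantedPair(atom_a=(c["res_a"], c["atom_a"]),
                    atom_b=(c["res_b"], c["atom_b"]),
                    distance=c["distance"], intended_type=c["type"])
        for c in profile.planted_contacts)
    return ContactFixtureSpec(residues=residues, planted_pairs=pairs,
                              decoy_min_distance=decoy_min_distance)


def build_fold_structure(profile: FoldProfile, seed: int = 0,
                         template: str | None = None) -> gemmi.Structure:
    """Synthetic stand-in structure for one fold."""
    structure = make_contact_fixture(fold_fixture_spec(profile, template),
                                     seed=seed)
    structure.name = f"synthetic-{profile.name}-{profile.pdb_id}"
    return structure


def build_fold_protomer(profile: FoldProfile, seed: int = 0,
                        template: str | None = None) -> Protomer:
    return select_protomer(build_fold_structure(profile, seed, template))


def build_all_fold_protomers(seed: int = 0) -> Mapping[str, Protomer]:
    """Stand-in protomers for all eight folds, keyed by fold name."""
    template = load_template()
    return {name: build_fold_protomer(profile, seed=seed, template=template)
            for name, profile in load_fold_profiles().items()}
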
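"""Reading fibril structures and typing atoms for contact classification.

A cryo-EM tau filament deposition contains many stacked chains (protomers);
the analyses in this package operate on a single protomer at a time.  This
module parses PDB/mmCIF files with gemmi, selects one protomer, extracts its
modeled sequence in author numbering, and assigns each heavy atom the three
chemical flags the contact engine needs: hydrogen-bond donor capability,
acceptor capability, and apolar-carbon status.

Atom typing is a pure function of (residue name, atom name), derived from
standard amino-acid connectivity: backbone N is a donor (except proline),
backbone O/OXT are acceptors, sidechain donors/acceptors follow textbook
chemistry, and an apolar carbon is a carbon not covalently bonded to N or O
in the residue template.  Cryo-EM depositions lack hydrogens, so the
hydrogen-bond criterion downstream is distance-only; sulfur (CYS SG, MET SD)
is treated as weakly donor/acceptor-capable by default and can be switched
off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import gemmi
import numpy as np

__all__ = [
    "Protomer",
    "ModeledSequence",
    "read_structure",
    "select_protomer",
    "extract_sequence",
    "atom_flags",
    "BACKBONE_ATOMS",
    "THREE_TO_ONE",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

# Sidechain donor / acceptor atoms per residue (heavy atoms only).
_SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
}

_SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
}

# Sulfur: no in-plane H in the model, but thiol/thioether sulfurs do form
# weak hydrogen bonds; included by default, disabled via sulfur_hbonds=False.
_SULFUR_DONORS = {"CYS": frozenset({"SG"}), "MET": frozenset({"SD"})}
_SULFUR_ACCEPTORS = _SULFUR_DONORS

# Sidechain carbons NOT bonded to N or O in the residue template.
_APOLAR_CARBONS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "ARG": frozenset({"CB", "CG"}),
    "ASN": frozenset({"CB"}),
    "ASP": frozenset({"CB"}),
    "CYS": frozenset({"CB"}),
    "GLN": frozenset({"CB", "CG"}),
    "GLU": frozenset({"CB", "CG"}),
    "GLY": frozenset(),
    "HIS": frozenset({"CB"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "LYS": frozenset({"CB", "CG", "CD"}),
    "MET": frozenset({"CB", "CG", "CE"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "PRO": frozenset({"CB", "CG"}),
    "SER": frozenset(),
    "THR": frozenset({"CG2"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def atom_flags(res_name: str, atom_name: str, *, sulfur_hbonds: bool = True
               ) -> tuple[bool, bool, bool]:
    """Return (is_donor, is_acceptor, is_apolar_carbon) for one heavy atom.

    Unknown residue names get backbone typing only; unknown atom names in
    known residues are untyped (all False), which the contact engine treats
    as inert.
    """
    res_name = res_name.upper()
    atom_name = atom_name.upper()
    if atom_name == "N":
        return (res_name != "PRO", False, False)
    if atom_name in ("O", "OXT"):
        return (False, True, False)
    if atom_name in ("CA", "C"):
        return (False, False, False)
    donor = atom_name in _SIDECHAIN_DONORS.get(res_name, frozenset())
    acceptor = atom_name in _SIDECHAIN_ACCEPTORS.get(res_name, frozenset())
    if sulfur_hbonds:
        donor = donor or atom_name in _SULFUR_DONORS.get(res_name, frozenset())
        acceptor = acceptor or atom_name in _SULFUR_ACCEPTORS.get(res_name, frozenset())
    apolar = atom_name in _APOLAR_CARBONS.get(res_name, frozenset())
    return (donor, acceptor, apolar)


@dataclass
class Protomer:
    """One fibril chain, flattened to parallel per-atom arrays.

    Author residue numbering is kept verbatim (tau depositions number
    residues on the 2N4R template, so e.g. Tyr310 keeps seq_id 310).
    Hydrogens are excluded; one altloc per atom.
    """

    source_id: str
    chain_id: str
    seq_ids: np.ndarray          # (n_atoms,) int author seq id per atom
    res_names: np.ndarray        # (n_atoms,) 3-letter code per atom
    atom_names: np.ndarray       # (n_atoms,) str
    coords: np.ndarray           # (n_atoms, 3) float Angstrom
    is_donor: np.ndarray         # (n_atoms,) bool
    is_acceptor: np.ndarray      # (n_atoms,) bool
    is_apolar: np.ndarray        # (n_atoms,) bool
    is_backbone: np.ndarray      # (n_atoms,) bool

    def __post_init__(self) -> None:
        n = len(self.seq_ids)
        for arr in (self.res_names, self.atom_names, self.is_donor,
                    self.is_acceptor, self.is_apolar, self.is_backbone):
            if len(arr) != n:
                raise ValueError("parallel atom arrays have unequal lengths")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates in protomer")

    @property
    def n_atoms(self) -> int:
        return len(self.seq_ids)

    def residues(self) -> list[tuple[int, str]]:
        """Ordered (author_seq_id, res_name) pairs of the modeled residues."""
        out: list[tuple[int, str]] = []
        seen: set[int] = set()
        for sid, rname in zip(self.seq_ids.tolist(), self.res_names.tolist()):
            if sid not in seen:
                seen.add(sid)
                out.append((sid, rname))
        return sorted(out)


@dataclass
class ModeledSequence:
    """One-letter sequence of the resolved residues with author numbering.

    ``gaps`` lists (id_before, id_after) wherever author numbering jumps by
    more than one — e.g. the Pick's fold protomer, built from 3R tau, jumps
    from 274 straight to 306 because R2 is absent from the isoform.
    """

    sequence: str
    seq_ids: list[int]
    gaps: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.seq_ids):
            raise ValueError("sequence and seq_id list lengths differ")
        if any(b <= a for a, b in zip(self.seq_ids, self.seq_ids[1:])):
            raise ValueError("author seq_ids must be strictly increasing")


def read_structure(path: str | Path,
                   format: Literal["pdb", "mmcif", "auto"] = "auto"
                   ) -> gemmi.Structure:
    """Read a structure file into a gemmi hierarchy.

    Waters are removed; non-standard residues are retained (gemmi flags them
    via het_flag).  Raises ValueError on an empty coordinate set and lets
    gemmi's parse errors (naming the offending record) propagate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        fmt = gemmi.CoorFormat.Detect
    elif format == "pdb":
        fmt = gemmi.CoorFormat.Pdb
    elif format == "mmcif":
        fmt = gemmi.CoorFormat.Mmcif
    else:
        raise ValueError(f"unknown format {format!r}")
    structure = gemmi.read_structure(str(path), format=fmt)
    structure.setup_entities()
    structure.remove_waters()
    n_atoms = sum(len(res) for model in structure
                  for chain in model for res in chain)
    if n_atoms == 0:
        raise ValueError(f"no atoms in {path}")
    return structure


def select_protomer(structure: gemmi.Structure,
                    chain: Optional[str] = None,
                    model: int = 0,
                    *,
                    sulfur_hbonds: bool = True) -> Protomer:
    """Select a single chain from one model and type its atoms.

    Defaults to the first model and the first polymer chain.  Altloc policy:
    keep blank or 'A', drop other conformers.  Hydrogens are dropped.
    """
    if model >= len(structure):
        raise IndexError(f"model {model} out of range ({len(structure)} models)")
    mdl = structure[model]
    chain_ids = [ch.name for ch in mdl]
    if chain is None:
        chosen = None
        for ch in mdl:
            if ch.get_polymer():
                chosen = ch
                break
        if chosen is None:
            chosen = mdl[0]
    else:
        chosen = None
        for ch in mdl:
            if ch.name == chain:
                chosen = ch
                break
        if chosen is None:
            raise KeyError(
                f"chain {chain!r} not found; available chains: {chain_ids}")

    seq_ids, res_names, atom_names = [], [], []
    coords, donors, acceptors, apolars, backbones = [], [], [], [], []
    for res in chosen:
        if res.is_water():
            continue
        for atom in res:
            if atom.is_hydrogen():
                continue
            if atom.altloc not in ("", "\0", "A"):
                continue
            d, a, ap = atom_flags(res.name, atom.name,
                                  sulfur_hbonds=sulfur_hbonds)
            seq_ids.append(res.seqid.num)
            res_names.append(res.name)
            atom_names.append(atom.name)
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            donors.append(d)
            acceptors.append(a)
            apolars.append(ap)
            backbones.append(atom.name in BACKBONE_ATOMS)

    if not seq_ids:
        raise ValueError(f"chain {chosen.name!r} has no heavy atoms")
    return Protomer(
        source_id=structure.name or "",
        chain_id=chosen.name,
        seq_ids=np.asarray(seq_ids, dtype=np.int64),
        res_names=np.asarray(res_names, dtype=object),
        atom_names=np.asarray(atom_names, dtype=object),
        coords=np.asarray(coords, dtype=np.float64),
        is_donor=np.asarray(donors, dtype=bool),
        is_acceptor=np.asarray(acceptors, dtype=bool),
        is_apolar=np.asarray(apolars, dtype=bool),
        is_backbone=np.asarray(backbones, dtype=bool),
    )


def extract_sequence(protomer: Protomer) -> ModeledSequence:
    """One-letter sequence of resolved residues; 'X' for unknown residues."""
    residues = protomer.residues()
    if not residues:
        raise ValueError("empty protomer")
    seq = "".join(THREE_TO_ONE.get(rname.upper(), "X") for _, rname in residues)
    ids = [sid for sid, _ in residues]
    gaps = [(a, b) for a, b in zip(ids, ids[1:]) if b - a > 1]
    return ModeledSequence(sequence=seq, seq_ids=ids, gaps=gaps)
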
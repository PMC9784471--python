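"""Synthetic structures and kinetic curves with exactly known ground truth.

Every downstream stage of the package — parsing, atom typing, contact
enumeration, motif profiling, kinetics calling — is testable offline against
fixtures produced here:

* contact fixtures: schematic protein chains whose residues sit on a coarse
  grid far beyond any contact cutoff, with selected atom pairs placed
  analytically at prescribed distances.  The emitted structure therefore
  contains exactly the planted contacts and provably nothing else;
* mini fibrils: several copies of a fixture chain stacked with a fixed rise
  (default 4.7 A, the canonical cross-beta spacing), to separate intra- from
  inter-chain contacts;
* ThT curves: logistic (aggregating) or flat (non-aggregating) fluorescence
  time series with additive Gaussian noise.

These are deliberately schematic: no physically realistic geometry, no
energy terms, no rotamers.  Only the planted distances are meaningful.
"""

from __future__ import annotations

import math
from typing import Literal

import gemmi
import numpy as np
from pydantic import BaseModel, Field, model_validator

from .kinetics import ThTCurve, logistic
from .structure import atom_flags

__all__ = [
    "RESIDUE_ATOMS", "PlantedPair", "ContactFixtureSpec", "MiniFibrilSpec",
    "ThTSimParams", "FixtureConstructionError",
    "make_contact_fixture", "make_minifibril", "simulate_tht",
]

# Heavy-atom inventory per standard residue (PDB atom names).
_BACKBONE = ("N", "CA", "C", "O")
_SIDECHAINS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}
RESIDUE_ATOMS: dict[str, tuple[str, ...]] = {
    res: _BACKBONE + side for res, side in _SIDECHAINS.items()
}

_JITTER = 0.7  # max per-axis atom offset from the residue anchor (A)


class FixtureConstructionError(RuntimeError):
    """Requested planted geometry is mutually unsatisfiable."""


class PlantedPair(BaseModel):
    model_config = {"frozen": True}

    atom_a: tuple[int, str]     # (seq_id, atom_name)
    atom_b: tuple[int, str]
    distance: float = Field(gt=0)
    intended_type: Literal["hbond", "hydrophobic", "none"]


class ContactFixtureSpec(BaseModel):
    """Residue inventory plus the atom pairs to plant at known distances."""

    model_config = {"frozen": True}

    residues: tuple[tuple[str, int, str], ...]   # (chain_id, seq_id, res_name)
    planted_pairs: tuple[PlantedPair, ...] = ()
    decoy_min_distance: float = Field(default=8.0, gt=0)

    @model_validator(mode="after")
    def _validate(self) -> "ContactFixtureSpec":
        keys = [(c, s) for c, s, _ in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain_id, seq_id) in residues")
        by_id = {s: r for _, s, r in self.residues}
        for r in {r for _, _, r in self.residues}:
            if r.upper() not in RESIDUE_ATOMS:
                raise ValueError(f"no atom template for residue {r!r}")
        for p in self.planted_pairs:
            for sid, aname in (p.atom_a, p.atom_b):
                if sid not in by_id:
                    raise ValueError(f"planted pair references seq_id {sid} "
                                     "absent from residues")
                if aname not in RESIDUE_ATOMS[by_id[sid].upper()]:
                    raise ValueError(
                        f"atom {aname!r} not in {by_id[sid]} template")
            fa = atom_flags(by_id[p.atom_a[0]], p.atom_a[1])
            fb = atom_flags(by_id[p.atom_b[0]], p.atom_b[1])
            if p.intended_type == "hbond":
                if not ((fa[0] and fb[1]) or (fa[1] and fb[0])):
                    raise ValueError(
                        f"hbond pair {p.atom_a}-{p.atom_b} is not "
                        "donor/acceptor capable")
            elif p.intended_type == "hydrophobic":
                if not (fa[2] and fb[2]):
                    raise ValueError(
                        f"hydrophobic pair {p.atom_a}-{p.atom_b} must join "
                        "two apolar carbons")
            else:  # decoy pair: must stay beyond both cutoffs by contract
                if p.distance <= 5.0:
                    raise ValueError(
                        "intended_type='none' pairs must be farther than "
                        "both cutoffs (> 5.0 A)")
        return self


class MiniFibrilSpec(BaseModel):
    model_config = {"frozen": True}

    protomer: ContactFixtureSpec
    n_layers: int = Field(default=1, ge=1)
    rise_per_layer: float = Field(default=4.7, gt=0)


class ThTSimParams(BaseModel):
    """Ground-truth parameters for one simulated ThT curve.

    Durations default to the 40-80 h window over which real tau/heparin
    reactions typically reach plateau.
    """

    model_config = {"frozen": True}

    amplitude: float = 100.0
    baseline: float = 10.0
    t50: float = 20.0
    rate_k: float = 0.5
    noise_sd: float = Field(default=2.0, ge=0)
    duration: float = Field(default=60.0, gt=0)
    n_points: int = Field(default=120, ge=10)
    aggregating: bool = True
    seed: int = 0


def _place_component(atoms: list[tuple[int, str]],
                     edges: dict[frozenset, float],
                     origin: np.ndarray) -> dict[tuple[int, str], np.ndarray]:
    """Place one connected component of planted atoms as a tree.

    Each atom is positioned at its prescribed distance from its BFS parent;
    edge directions rotate through a fixed set of well-separated unit
    vectors so sibling branches diverge.  A cyclic constraint graph is
    rejected: simultaneous exact distances around a cycle are not in
    general satisfiable by this construction.
    """
    # first direction is an exact axis so an isolated pair realises its
    # distance bit-exactly (ties at a cutoff stay ties)
    directions = [np.array([1.0, 0.0, 0.0])]
    golden = math.pi * (3 - math.sqrt(5))
    for k in range(1, 32):
        z = 1 - 2 * (k + 0.5) / 32
        r = math.sqrt(max(0.0, 1 - z * z))
        directions.append(np.array([r * math.cos(golden * k),
                                    r * math.sin(golden * k), z]))
    pos: dict[tuple[int, str], np.ndarray] = {atoms[0]: origin.copy()}
    queue = [atoms[0]]
    seen_edges: set[frozenset] = set()
    d_idx = 0
    while queue:
        cur = queue.pop(0)
        for edge, dist in edges.items():
            if cur not in edge or edge in seen_edges:
                continue
            other = next(a for a in edge if a != cur)
            if other in pos:
                raise FixtureConstructionError(
                    f"cyclic planted-pair constraints around {other}")
            seen_edges.add(edge)
            pos[other] = pos[cur] + dist * directions[d_idx % len(directions)]
            d_idx += 1
            queue.append(other)
    return pos


def make_contact_fixture(spec: ContactFixtureSpec,
                         seed: int = 0) -> gemmi.Structure:
    """Build a structure realising the fixture spec exactly.

    Residue anchors sit on a widely spaced grid (spacing exceeds the decoy
    minimum plus the largest planted distance), each atom jittered within
    +-0.7 A of its anchor; planted atoms are then moved to analytic
    positions in a separate row of the grid.  After construction every
    planted distance is verified to 1e-6 A and every non-planted
    inter-residue pair is verified to exceed ``decoy_min_distance``;
    violations raise FixtureConstructionError.
    """
    rng = np.random.default_rng(seed)
    d_max = max((p.distance for p in spec.planted_pairs), default=0.0)
    spacing = spec.decoy_min_distance + d_max + 2 * _JITTER + 2.0

    # ordered atom list per residue
    atom_pos: dict[tuple[int, str], np.ndarray] = {}
    residue_order = sorted(spec.residues, key=lambda r: (r[0], r[1]))
    for idx, (_, seq_id, res_name) in enumerate(residue_order):
        anchor = np.array([idx * spacing, 0.0, 0.0])
        for aname in RESIDUE_ATOMS[res_name.upper()]:
            jitter = rng.uniform(-_JITTER, _JITTER, size=3)
            atom_pos[(seq_id, aname)] = anchor + jitter

    # planted components, placed in a distant second row
    edges: dict[frozenset, float] = {}
    for p in spec.planted_pairs:
        key = frozenset((p.atom_a, p.atom_b))
        if key in edges and edges[key] != p.distance:
            raise FixtureConstructionError(
                f"pair {p.atom_a}-{p.atom_b} planted at two distances")
        edges[key] = p.distance
    adjacency: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for edge in edges:
        a, b = tuple(edge)
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
    visited: set[tuple[int, str]] = set()
    row_y = -(spec.decoy_min_distance + d_max + 10.0)
    comp_idx = 0
    for atom in sorted(adjacency):
        if atom in visited:
            continue
        component = []
        stack = [atom]
        while stack:
            cur = stack.pop()
            if cur in visited:
                continue
            visited.add(cur)
            component.append(cur)
            stack.extend(adjacency[cur])
        comp_edges = {e: d for e, d in edges.items()
                      if all(a in component for a in e)}
        origin = np.array([comp_idx * spacing, row_y, 0.0])
        atom_pos.update(_place_component(sorted(component), comp_edges, origin))
        comp_idx += 1

    _verify_fixture(spec, atom_pos)
    return _assemble(spec, atom_pos)


def _verify_fixture(spec: ContactFixtureSpec,
                    atom_pos: dict[tuple[int, str], np.ndarray]) -> None:
    planted = {frozenset((p.atom_a, p.atom_b)): p.distance
               for p in spec.planted_pairs}
    for key, want in planted.items():
        a, b = tuple(key)
        got = float(np.linalg.norm(atom_pos[a] - atom_pos[b]))
        if abs(got - want) > 1e-6:
            raise FixtureConstructionError(
                f"planted pair {a}-{b}: requested {want}, realised {got}")
    names = sorted(atom_pos)
    coords = np.array([atom_pos[n] for n in names])
    resid = np.array([n[0] for n in names])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    mask = np.triu(np.ones(len(names), dtype=bool), k=1)
    mask &= resid[:, None] != resid[None, :]   # intra-residue unconstrained
    index_of = {n: k for k, n in enumerate(names)}
    for key in planted:
        a, b = tuple(key)
        mask[index_of[a], index_of[b]] = False
        mask[index_of[b], index_of[a]] = False
    bad = mask & (d <= spec.decoy_min_distance)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise FixtureConstructionError(
            f"infeasible geometry: non-planted pair {names[i]}-{names[j]} "
            f"at {d[i, j]:.2f} A <= decoy minimum {spec.decoy_min_distance}")


def _assemble(spec: ContactFixtureSpec,
              atom_pos: dict[tuple[int, str], np.ndarray],
              *, extra_layers: int = 0, rise: float = 0.0) -> gemmi.Structure:
    structure = gemmi.Structure()
    structure.name = "synthetic-fixture"
    model = gemmi.Model("1")
    chain_names = [c for c, _, _ in spec.residues]
    base_chain = chain_names[0] if chain_names else "A"
    layer_ids = _chain_series(base_chain, extra_layers + 1)
    for layer in range(extra_layers + 1):
        chain = gemmi.Chain(layer_ids[layer])
        dz = layer * rise
        for _, seq_id, res_name in sorted(spec.residues,
                                          key=lambda r: (r[0], r[1])):
            res = gemmi.Residue()
            res.name = res_name.upper()
            res.seqid = gemmi.SeqId(seq_id, " ")
            for aname in RESIDUE_ATOMS[res_name.upper()]:
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(aname[0])
                x, y, z = atom_pos[(seq_id, aname)]
                atom.pos = gemmi.Position(float(x), float(y), float(z + dz))
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    return structure


def _chain_series(first: str, n: int) -> list[str]:
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    start = alphabet.index(first) if first in alphabet else 0
    return [alphabet[(start + k) % len(alphabet)] for k in range(n)]


def make_minifibril(spec: MiniFibrilSpec, seed: int = 0) -> gemmi.Structure:
    """Stack n_layers copies of the protomer fixture along z.

    Chains are lettered consecutively; equivalent atoms in adjacent layers
    are exactly ``rise_per_layer`` apart and intra-chain geometry is
    identical across layers.
    """
    # reuse the fixture placement (same seed stream as make_contact_fixture)
    single = make_contact_fixture(spec.protomer, seed=seed)
    atom_pos: dict[tuple[int, str], np.ndarray] = {}
    for res in single[0][0]:
        for atom in res:
            atom_pos[(res.seqid.num, atom.name)] = np.array(
                [atom.pos.x, atom.pos.y, atom.pos.z])
    return _assemble(spec.protomer, atom_pos,
                     extra_layers=spec.n_layers - 1,
                     rise=spec.rise_per_layer)


def simulate_tht(params: ThTSimParams) -> ThTCurve:
    """Simulate one ThT fluorescence curve.

    Aggregating: logistic sigmoid plus Gaussian noise; otherwise flat
    baseline plus noise.  Byte-reproducible for a fixed parameter set
    (the seed is part of the parameters).
    """
    rng = np.random.default_rng(params.seed)
    t = np.linspace(0.0, params.duration, params.n_points)
    if params.aggregating:
        y = logistic(t, params.baseline, params.amplitude,
                     params.t50, params.rate_k)
    else:
        y = np.full_like(t, params.baseline)
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=t.shape)
    return ThTCurve(time=t, fluorescence=y,
                    metadata={"aggregating": params.aggregating,
                              "seed": params.seed,
                              "true_t50": params.t50 if params.aggregating
                              else None})
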
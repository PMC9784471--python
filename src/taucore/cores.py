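"""Nucleation-core motif scanning, strain classification, truncation loss.

Tau aggregation nucleates at two hexapeptides in the microtubule-binding
region: VQIINK (PHF6*, residues 275-280, start of repeat R2) and VQIVYK
(PHF6, residues 306-311, start of repeat R3).  Protofilament folds from
different tauopathies order one or both hexamers in their rigid core, which
splits the known strains into single-core (only PHF6 ordered) and dual-core
(PHF6 and PHF6*) classes.

The truncation-loss analysis asks what the structural neighbourhood loses
when the last three residues of a hexamer are removed (VYK 309-311 from
PHF6, INK 278-280 from PHF6*): every residue-pair interaction that involves
a removed residue and reaches outside the motif disappears.  Comparing the
size of these neighbourhoods between the two cores ranks PHF6 as primary
wherever it carries at least as many interactions as PHF6*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

from .contacts import (ContactParams, ResiduePairInteraction,
                       aggregate_residue_pairs, find_contacts)
from .structure import ModeledSequence, Protomer

__all__ = [
    "Motif", "MotifHit", "StrainClass", "LossReport", "CoreRank",
    "PHF6", "PHF6_STAR", "VQI", "DEFAULT_MOTIFS",
    "scan_motifs", "classify_fold", "truncation_loss", "rank_cores",
]


@dataclass(frozen=True)
class Motif:
    """A nucleation motif; suffix_len is the tail removed in truncation
    analysis (3 for the VYK / INK tails of the hexamers)."""

    name: str
    sequence: str
    suffix_len: int = 3

    def __post_init__(self) -> None:
        if not self.sequence or not re.fullmatch(r"[ACDEFGHIKLMNPQRSTVWY]+",
                                                 self.sequence):
            raise ValueError(f"invalid motif sequence {self.sequence!r}")
        if not 0 <= self.suffix_len <= len(self.sequence):
            raise ValueError("suffix_len outside motif length")


PHF6 = Motif("PHF6", "VQIVYK", 3)
PHF6_STAR = Motif("PHF6*", "VQIINK", 3)
VQI = Motif("VQI", "VQI", 0)
DEFAULT_MOTIFS = (PHF6, PHF6_STAR)
_CORE_NAMES = frozenset({PHF6.name, PHF6_STAR.name})


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a motif in a modeled sequence (author numbering).

    ``fully_resolved`` is False when the occurrence spans a numbering gap,
    i.e. the motif letters are present in the concatenated modeled string
    but not as six consecutively numbered residues.
    """

    motif: Motif
    start_seq_id: int
    end_seq_id: int
    fully_resolved: bool

    @property
    def motif_name(self) -> str:
        return self.motif.name

    @property
    def seq_id_range(self) -> range:
        return range(self.start_seq_id, self.end_seq_id + 1)

    @property
    def removed_seq_ids(self) -> list[int]:
        """Author seq_ids of the suffix residues dropped by truncation."""
        return list(range(self.end_seq_id - self.motif.suffix_len + 1,
                          self.end_seq_id + 1))


@dataclass(frozen=True)
class StrainClass:
    label: Literal["single_core", "dual_core", "no_core"]
    cores_present: frozenset[str]
    core_contact_counts: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class LossReport:
    """Residue-pair interactions lost when a motif suffix is removed."""

    fold_id: str
    motif_name: str
    removed_seq_ids: tuple[int, ...]
    lost_pairs: tuple[ResiduePairInteraction, ...]

    @property
    def n_lost(self) -> int:
        return len(self.lost_pairs)

    @property
    def lost_pair_ids(self) -> set[tuple[int, int]]:
        return {p.seq_ids for p in self.lost_pairs}


@dataclass(frozen=True)
class CoreRank:
    motif_name: str
    n_pairs: int
    rank: int          # 1 = primary
    tied: bool


def scan_motifs(seq: ModeledSequence,
                motifs: Sequence[Motif] = DEFAULT_MOTIFS) -> list[MotifHit]:
    """All (overlapping) occurrences of each motif in the modeled sequence.

    An occurrence is fully resolved when its residues carry consecutive
    author seq_ids; occurrences assembled across a numbering gap are
    reported but flagged unresolved.
    """
    hits: list[MotifHit] = []
    for motif in motifs:
        pattern = re.compile("(?=" + re.escape(motif.sequence) + ")")
        n = len(motif.sequence)
        for m in pattern.finditer(seq.sequence):
            i = m.start()
            start_id = seq.seq_ids[i]
            end_id = seq.seq_ids[i + n - 1]
            hits.append(MotifHit(
                motif=motif, start_seq_id=start_id, end_seq_id=end_id,
                fully_resolved=(end_id - start_id + 1 == n)))
    hits.sort(key=lambda h: (h.start_seq_id, h.motif_name))
    return hits


def classify_fold(hits: Sequence[MotifHit],
                  core_contact_counts: Optional[dict[str, int]] = None
                  ) -> StrainClass:
    """Single/dual/no-core strain label from resolved hexamer hits.

    Only fully resolved PHF6 / PHF6* occurrences count as ordered cores;
    the motif letters merely being present in the isoform sequence is not
    enough (the single-core folds are built from tau that contains VQIINK,
    yet do not order it).
    """
    cores = frozenset(h.motif_name for h in hits
                      if h.fully_resolved and h.motif_name in _CORE_NAMES)
    if len(cores) == 2:
        label = "dual_core"
    elif len(cores) == 1:
        label = "single_core"
    else:
        label = "no_core"
    return StrainClass(label=label, cores_present=cores,
                       core_contact_counts=dict(core_contact_counts or {}))


def truncation_loss(protomer: Protomer, hit: MotifHit,
                    params: ContactParams | None = None,
                    *, fold_id: str = "") -> LossReport:
    """Interactions lost when the motif's suffix residues are removed.

    Keeps residue pairs with at least one member among the removed suffix
    residues, excluding pairs internal to the motif (the analysis concerns
    the motif's anchoring to the rest of the fold, not its self-packing).
    """
    if not hit.fully_resolved:
        raise ValueError(
            f"{hit.motif_name} at {hit.start_seq_id} is not fully resolved "
            "on this protomer; truncation loss is undefined")
    removed = set(hit.removed_seq_ids)
    motif_ids = set(hit.seq_id_range)
    pairs = aggregate_residue_pairs(find_contacts(protomer, params))
    lost = tuple(
        p for p in pairs
        if (p.residue_a[0] in removed or p.residue_b[0] in removed)
        and not (p.residue_a[0] in motif_ids and p.residue_b[0] in motif_ids))
    return LossReport(fold_id=fold_id or protomer.source_id,
                      motif_name=hit.motif_name,
                      removed_seq_ids=tuple(sorted(removed)),
                      lost_pairs=lost)


def rank_cores(reports: Sequence[LossReport]) -> list[CoreRank]:
    """Order cores by how many residue-pair interactions anchor them.

    Descending interaction count; ties broken alphabetically by motif name
    and flagged.  The top rank is the putative primary nucleation core.
    """
    if not reports:
        raise ValueError("rank_cores requires at least one loss report")
    ordered = sorted(reports, key=lambda r: (-r.n_lost, r.motif_name))
    counts = [r.n_lost for r in ordered]
    return [
        CoreRank(motif_name=r.motif_name, n_pairs=r.n_lost, rank=i + 1,
                 tied=counts.count(r.n_lost) > 1)
        for i, r in enumerate(ordered)
    ]
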
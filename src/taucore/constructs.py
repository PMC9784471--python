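"""Tau isoform and truncation/extension construct design.

The longest human tau isoform, 2N4R (441 residues), is the template: two
N-terminal inserts (N1, N2), a proline-rich region, four microtubule-binding
repeats R1-R4, and the C-tail.  The six brain isoforms arise from dropping
N1/N2 and/or the R2 repeat.  Truncation series walk cut points across the
domain boundaries from either terminus (N1-N8 from the N-terminus, C1-C5
from the C-terminus); three extension constructs append a single nucleation
motif to the non-amyloidogenic C4 carrier: VQIINK (C6), VQIVYK (C7, built on
the 2N3R parent where R3 directly joins R1), or the three-residue consensus
VQI (C8).

The amyloidogenicity rule is deliberately simple and falsifiable: a
construct is predicted competent iff it contains an intact copy of either
hexamer, VQIVYK or VQIINK.  The trimeric consensus VQI does not qualify.

Experimentally observed outcomes (ThT-positive or not) are attached to the
constructs as labels where known.  Note the N-series default cut table is a
domain-boundary reconstruction: under it N7 starts at residue 306 and so
still contains PHF6, while the observed N7 outcome is negative — the
published construct endpoints are not recoverable from the text, so
N-series outcomes are reported but never used to score the predictor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "TauDomainMap", "ConstructSpec", "ConstructSeq",
    "load_template", "load_domain_map", "make_isoform",
    "build_isoforms", "build_truncation_series",
    "build_extension_constructs", "predict_amyloidogenic", "write_fasta",
    "DEFAULT_N_CUTS", "DEFAULT_C_CUTS", "OBSERVED_OUTCOMES",
    "PHF6_SEQ", "PHF6_STAR_SEQ",
]

log = logging.getLogger(__name__)

PHF6_SEQ = "VQIVYK"
PHF6_STAR_SEQ = "VQIINK"

_DOMAIN_ORDER = ("N_head", "N1_insert", "N2_insert", "mid", "proline_rich",
                 "R1", "R2", "R3", "R4", "C_tail")

# One cut per internal domain boundary (2N4R numbering).
DEFAULT_N_CUTS = (45, 74, 103, 151, 244, 275, 306, 337)
DEFAULT_C_CUTS = (368, 336, 305, 274, 243)

ISOFORM_NAMES = ("2N4R", "1N4R", "0N4R", "2N3R", "1N3R", "0N3R")

# ThT outcomes of the published constructs (qualitative labels).
OBSERVED_OUTCOMES: dict[str, bool] = {
    **{f"N{i}": True for i in range(1, 7)},
    "N7": False, "N8": False,
    "C1": True, "C2": True, "C3": True, "C4": False, "C5": False,
    "C6": True, "C7": True, "C8": False,
    **{name: True for name in ISOFORM_NAMES},
}


class TauDomainMap(BaseModel):
    """Named 1-based closed intervals tiling the 2N4R template."""

    model_config = {"frozen": True}

    template_length: int = Field(gt=0)
    intervals: dict[str, tuple[int, int]]

    @model_validator(mode="after")
    def _contiguous_cover(self) -> "TauDomainMap":
        missing = [n for n in _DOMAIN_ORDER if n not in self.intervals]
        if missing:
            raise ValueError(f"domain map missing intervals: {missing}")
        expected_start = 1
        for name in _DOMAIN_ORDER:
            start, end = self.intervals[name]
            if start != expected_start or end < start:
                raise ValueError(
                    f"interval {name} [{start},{end}] breaks contiguous "
                    f"coverage (expected start {expected_start})")
            expected_start = end + 1
        if expected_start != self.template_length + 1:
            raise ValueError("intervals do not cover 1..template_length")
        return self

    def interval(self, name: str) -> tuple[int, int]:
        return self.intervals[name]

    def validate_template(self, template: str) -> None:
        """Check template length and the motif anchors at R2/R3 starts."""
        if len(template) != self.template_length:
            raise ValueError(
                f"template length {len(template)} != map "
                f"template_length {self.template_length}")
        r2, r3 = self.intervals["R2"][0], self.intervals["R3"][0]
        if template[r2 - 1:r2 + 5] != PHF6_STAR_SEQ:
            raise ValueError(f"R2 does not begin with {PHF6_STAR_SEQ} "
                             f"at {r2}")
        if template[r3 - 1:r3 + 5] != PHF6_SEQ:
            raise ValueError(f"R3 does not begin with {PHF6_SEQ} at {r3}")


@dataclass(frozen=True)
class ConstructSpec:
    """Design of one construct on a parent template's numbering."""

    name: str
    parent: Literal["2N4R", "2N3R"]
    retained_intervals: tuple[tuple[int, int], ...]
    appended_motif: Optional[str] = None


@dataclass(frozen=True)
class ConstructSeq:
    """A realised construct sequence with its amyloidogenicity labels."""

    spec: ConstructSpec
    sequence: str
    predicted_amyloidogenic: bool
    observed_amyloidogenic: Optional[bool] = None

    def __post_init__(self) -> None:
        expect = sum(e - s + 1 for s, e in self.spec.retained_intervals)
        expect += len(self.spec.appended_motif or "")
        if len(self.sequence) != expect:
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} != "
                f"retained intervals + appended motif ({expect})")

    @property
    def name(self) -> str:
        return self.spec.name

    @property
    def length(self) -> int:
        return len(self.sequence)


def load_template() -> str:
    """The packaged canonical human tau 2N4R sequence (441 residues)."""
    with resources.files("taucore.data").joinpath("tau_2n4r.fasta").open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return str(record.seq)


def load_domain_map(path: str | Path | None = None) -> TauDomainMap:
    """Domain boundaries from JSON; defaults to the packaged table."""
    if path is None:
        raw = resources.files("taucore.data").joinpath(
            "domain_map.json").read_text()
    else:
        raw = Path(path).read_text()
    data = json.loads(raw)
    return TauDomainMap(
        template_length=data["template_length"],
        intervals={k: tuple(v) for k, v in data["intervals"].items()})


def _realise(spec: ConstructSpec, parents: Mapping[str, str],
             observed: Optional[bool] = None) -> ConstructSeq:
    template = parents[spec.parent]
    seq = "".join(template[s - 1:e] for s, e in spec.retained_intervals)
    seq += spec.appended_motif or ""
    return ConstructSeq(spec=spec, sequence=seq,
                        predicted_amyloidogenic=predict_amyloidogenic(seq),
                        observed_amyloidogenic=observed)


def _drop_intervals(template_len: int,
                    dropped: Sequence[tuple[int, int]]
                    ) -> tuple[tuple[int, int], ...]:
    """Complement of the dropped intervals, as retained intervals."""
    retained = []
    pos = 1
    for s, e in sorted(dropped):
        if pos <= s - 1:
            retained.append((pos, s - 1))
        pos = e + 1
    if pos <= template_len:
        retained.append((pos, template_len))
    return tuple(retained)


def make_isoform(name: str, domain_map: TauDomainMap,
                 template: str) -> ConstructSeq:
    """Build one of the six isoforms by dropping inserts and/or R2."""
    if name not in ISOFORM_NAMES:
        raise ValueError(f"unknown isoform {name!r}; expected one of "
                         f"{ISOFORM_NAMES}")
    dropped: list[tuple[int, int]] = []
    n_inserts = int(name[0])
    if n_inserts == 0:
        dropped.append((domain_map.interval("N1_insert")[0],
                        domain_map.interval("N2_insert")[1]))
    elif n_inserts == 1:
        dropped.append(domain_map.interval("N2_insert"))
    if name.endswith("3R"):
        dropped.append(domain_map.interval("R2"))
    spec = ConstructSpec(
        name=name, parent="2N4R",
        retained_intervals=_drop_intervals(len(template), dropped))
    return _realise(spec, {"2N4R": template},
                    observed=OBSERVED_OUTCOMES.get(name))


def build_isoforms(domain_map: TauDomainMap,
                   template: str) -> list[ConstructSeq]:
    """All six brain isoforms; 2N4R reproduces the template exactly."""
    domain_map.validate_template(template)
    return [make_isoform(name, domain_map, template)
            for name in ISOFORM_NAMES]


def build_truncation_series(domain_map: TauDomainMap, template: str,
                            direction: Literal["n_terminal", "c_terminal"],
                            boundaries: Optional[Sequence[int]] = None
                            ) -> list[ConstructSeq]:
    """Serial single-cut truncations of the template.

    n_terminal: construct k retains [cut_k, end] (cuts ascending);
    c_terminal: construct k retains [1, cut_k] (cuts descending, i.e.
    progressively shorter).  Cut points must be strictly monotone and lie
    inside the template.
    """
    domain_map.validate_template(template)
    if direction == "n_terminal":
        cuts = tuple(boundaries) if boundaries is not None else DEFAULT_N_CUTS
        prefix, ascending = "N", True
    elif direction == "c_terminal":
        cuts = tuple(boundaries) if boundaries is not None else DEFAULT_C_CUTS
        prefix, ascending = "C", False
    else:
        raise ValueError(f"unknown direction {direction!r}")
    diffs = [b - a for a, b in zip(cuts, cuts[1:])]
    if ascending and any(d <= 0 for d in diffs):
        raise ValueError("n-terminal cut points must be strictly increasing")
    if not ascending and any(d >= 0 for d in diffs):
        raise ValueError("c-terminal cut points must be strictly decreasing")
    if any(not 1 <= c <= len(template) for c in cuts):
        raise ValueError("cut points outside the template")

    out = []
    for k, cut in enumerate(cuts, start=1):
        interval = (cut, len(template)) if direction == "n_terminal" \
            else (1, cut)
        name = f"{prefix}{k}"
        spec = ConstructSpec(name=name, parent="2N4R",
                             retained_intervals=(interval,))
        out.append(_realise(spec, {"2N4R": template},
                            observed=OBSERVED_OUTCOMES.get(name)
                            if boundaries is None else None))
    return out


def build_extension_constructs(domain_map: TauDomainMap,
                               templates: Mapping[str, str]
                               ) -> list[ConstructSeq]:
    """The motif-extension constructs C6, C7, C8.

    All three share the C4 carrier (template through the end of R1, the
    longest C-terminal truncation with no intact hexamer).  C6 appends
    VQIINK (2N4R parent: R2 begins right after R1, so the extension equals
    resuming the parent for six residues).  C7 ends in VQIVYK and is built
    on the 2N3R parent, where R3 directly joins R1.  C8 appends only the
    consensus VQI.
    """
    if "2N4R" not in templates:
        raise KeyError("2N4R template required")
    if "2N3R" not in templates:
        raise KeyError("C7 requires the 2N3R parent template; none supplied")
    t4 = templates["2N4R"]
    domain_map.validate_template(t4)
    r1_end = domain_map.interval("R1")[1]
    r2 = domain_map.interval("R2")
    t3 = templates["2N3R"]
    expected_3r = t4[:r2[0] - 1] + t4[r2[1]:]
    if t3 != expected_3r:
        raise ValueError("2N3R template does not equal 2N4R minus R2")

    specs = [
        ConstructSpec(name="C6", parent="2N4R",
                      retained_intervals=((1, r1_end),),
                      appended_motif=PHF6_STAR_SEQ),
        # 2N3R numbering: positions 1..r1_end are identical to 2N4R, and
        # VQIVYK follows immediately (R3 joins R1).
        ConstructSpec(name="C7", parent="2N3R",
                      retained_intervals=((1, r1_end + 6),)),
        ConstructSpec(name="C8", parent="2N4R",
                      retained_intervals=((1, r1_end),),
                      appended_motif="VQI"),
    ]
    return [_realise(s, {"2N4R": t4, "2N3R": t3},
                     observed=OBSERVED_OUTCOMES.get(s.name)) for s in specs]


def predict_amyloidogenic(seq: "str | ConstructSeq") -> bool:
    """True iff the sequence contains an intact VQIVYK or VQIINK hexamer."""
    s = seq.sequence if isinstance(seq, ConstructSeq) else str(seq)
    return PHF6_SEQ in s or PHF6_STAR_SEQ in s


def write_fasta(constructs: Sequence[ConstructSeq],
                path: str | Path) -> None:
    """Write constructs as FASTA (60-column wrap, annotated headers)."""
    names = [c.name for c in constructs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate construct names")
    if not constructs:
        log.warning("writing empty FASTA to %s", path)
    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description=(
            f"length={c.length} predicted_amyloidogenic="
            f"{'yes' if c.predicted_amyloidogenic else 'no'}"))
        for c in constructs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
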
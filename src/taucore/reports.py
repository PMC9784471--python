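"""Assembly of the two top-level analyses into tabular reports.

`classify_protomers` runs the structural pipeline per protomer: modeled
sequence -> motif scan -> strain class -> truncation-loss reports for each
resolved core -> primary/secondary core ranking.  `constructs_report`
rebuilds the full construct panel (six isoforms, N1-N8, C1-C5, C6-C8) and
scores the hexamer amyloidogenicity rule against the recorded experimental
outcomes, flagging where the two disagree.

Every classification report embeds the distance cutoffs it was computed
with, so a table is self-describing.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from .contacts import ContactParams
from .constructs import (TauDomainMap, build_extension_constructs,
                         build_isoforms, build_truncation_series,
                         load_domain_map, load_template)
from .cores import (DEFAULT_MOTIFS, LossReport, classify_fold, rank_cores,
                    scan_motifs, truncation_loss)
from .structure import Protomer, extract_sequence

__all__ = ["classify_protomers", "constructs_report", "build_all_constructs"]


def _fmt_pairs(report: Optional[LossReport]) -> str:
    if report is None:
        return ""
    return ";".join(f"{a}-{b}" for a, b in sorted(report.lost_pair_ids))


def classify_protomers(protomers: Mapping[str, Protomer],
                       params: ContactParams | None = None
                       ) -> tuple[pd.DataFrame, dict]:
    """One classification row per protomer, plus full per-fold details.

    Returns (table, details) where details maps fold id to its motif hits,
    strain class, loss reports and core ranking.
    """
    params = params or ContactParams()
    rows = []
    details: dict[str, dict] = {}
    for fold_id, protomer in protomers.items():
        seq = extract_sequence(protomer)
        hits = scan_motifs(seq, DEFAULT_MOTIFS)
        reports: dict[str, LossReport] = {}
        for hit in hits:
            if hit.fully_resolved and hit.motif_name not in reports:
                reports[hit.motif_name] = truncation_loss(
                    protomer, hit, params, fold_id=fold_id)
        counts = {name: r.n_lost for name, r in reports.items()}
        strain = classify_fold(hits, counts)
        ranking = rank_cores(list(reports.values())) if reports else []
        primary = ranking[0].motif_name if ranking else ""
        rows.append({
            "fold": fold_id,
            "class": strain.label,
            "cores_present": ";".join(sorted(strain.cores_present)),
            "n_pairs_PHF6": counts.get("PHF6", 0),
            "n_pairs_PHF6star": counts.get("PHF6*", 0),
            "primary_core": primary,
            "ranking_tied": bool(ranking and ranking[0].tied),
            "lost_pairs_PHF6": _fmt_pairs(reports.get("PHF6")),
            "lost_pairs_PHF6star": _fmt_pairs(reports.get("PHF6*")),
            "hbond_max_A": params.hbond_max,
            "hydrophobic_max_A": params.hydrophobic_max,
        })
        details[fold_id] = {"sequence": seq, "hits": hits, "strain": strain,
                            "loss_reports": reports, "ranking": ranking}
    return pd.DataFrame(rows), details


def build_all_constructs(domain_map: TauDomainMap | None = None,
                         template: str | None = None):
    """The full 22-construct panel: isoforms + N-series + C-series + C6-C8."""
    domain_map = domain_map or load_domain_map()
    template = template or load_template()
    r2 = domain_map.interval("R2")
    template_3r = template[:r2[0] - 1] + template[r2[1]:]
    panel = []
    panel += build_isoforms(domain_map, template)
    panel += build_truncation_series(domain_map, template, "n_terminal")
    panel += build_truncation_series(domain_map, template, "c_terminal")
    panel += build_extension_constructs(
        domain_map, {"2N4R": template, "2N3R": template_3r})
    return panel


def constructs_report(domain_map: TauDomainMap | None = None,
                      template: str | None = None) -> pd.DataFrame:
    """Tabular construct panel with predictions vs recorded outcomes.

    The ``note`` column flags records where the hexamer rule disagrees with
    the recorded ThT outcome — under the default domain-boundary cut table
    this happens for N7, whose published endpoint cannot be reconstructed
    exactly (the rule is scored on the C-series and extensions only).
    """
    panel = build_all_constructs(domain_map, template)

    def group_of(name: str) -> str:
        if name in ("C6", "C7", "C8"):
            return "extension"
        if name.startswith("N") and name[1:].isdigit():
            return "n_series"
        if name.startswith("C") and name[1:].isdigit():
            return "c_series"
        return "isoform"

    rows = []
    for c in panel:
        note = ""
        if (c.observed_amyloidogenic is not None
                and c.observed_amyloidogenic != c.predicted_amyloidogenic):
            note = ("prediction differs from recorded outcome; construct "
                    "endpoint reconstruction uncertain")
        rows.append({
            "name": c.name,
            "group": group_of(c.name),
            "parent": c.spec.parent,
            "length": c.length,
            "predicted_amyloidogenic": c.predicted_amyloidogenic,
            "observed_amyloidogenic": c.observed_amyloidogenic,
            "note": note,
        })
    return pd.DataFrame(rows)
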
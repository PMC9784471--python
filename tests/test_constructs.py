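"""Isoform/truncation/extension construct design and the hexamer rule."""

import pytest
from Bio import SeqIO
from hypothesis import given, settings
from hypothesis import strategies as st

from taucore.constructs import (DEFAULT_C_CUTS, DEFAULT_N_CUTS,
                                OBSERVED_OUTCOMES, TauDomainMap,
                                build_extension_constructs, build_isoforms,
                                build_truncation_series, load_domain_map,
                                predict_amyloidogenic, write_fasta)
from taucore.cores import DEFAULT_MOTIFS, scan_motifs
from taucore.reports import build_all_constructs
from taucore.structure import ModeledSequence


@pytest.fixture(scope="module")
def both_templates(template=None):
    from taucore.constructs import load_template
    t4 = load_template()
    dm = load_domain_map()
    r2 = dm.interval("R2")
    return dm, {"2N4R": t4, "2N3R": t4[:r2[0] - 1] + t4[r2[1]:]}


class TestDomainMap:
    def test_packaged_map_valid(self, domain_map, template):
        domain_map.validate_template(template)
        assert domain_map.template_length == 441

    def test_non_contiguous_rejected(self):
        good = load_domain_map()
        intervals = dict(good.intervals)
        intervals["R2"] = (275, 304)  # leaves 305 uncovered
        with pytest.raises(ValueError, match="contiguous"):
            TauDomainMap(template_length=441, intervals=intervals)

    def test_template_mismatch_rejected(self, domain_map):
        with pytest.raises(ValueError):
            domain_map.validate_template("A" * 441)


class TestIsoforms:
    def test_six_isoforms_2n4r_identity(self, domain_map, template):
        isoforms = build_isoforms(domain_map, template)
        assert len(isoforms) == 6
        by_name = {c.name: c for c in isoforms}
        assert by_name["2N4R"].sequence == template
        assert by_name["0N3R"].length == min(c.length for c in isoforms)
        assert by_name["2N4R"].length == max(c.length for c in isoforms)

    def test_3r_isoforms_lack_vqiink_keep_vqivyk(self, domain_map, template):
        for c in build_isoforms(domain_map, template):
            assert "VQIVYK" in c.sequence
            if c.name.endswith("3R"):
                assert "VQIINK" not in c.sequence
            else:
                assert "VQIINK" in c.sequence

    def test_known_isoform_lengths(self, domain_map, template):
        lengths = {c.name: c.length
                   for c in build_isoforms(domain_map, template)}
        assert lengths == {"2N4R": 441, "1N4R": 412, "0N4R": 383,
                           "2N3R": 410, "1N3R": 381, "0N3R": 352}

    def test_drop_order_commutative(self, domain_map, template):
        """0N3R via (drop inserts, drop R2) equals the direct construction
        regardless of conceptual order: check against manual splice."""
        by_name = {c.name: c for c in build_isoforms(domain_map, template)}
        n1 = domain_map.interval("N1_insert")
        n2 = domain_map.interval("N2_insert")
        r2 = domain_map.interval("R2")
        manual = (template[:n1[0] - 1] + template[n2[1]:r2[0] - 1]
                  + template[r2[1]:])
        assert by_name["0N3R"].sequence == manual


class TestTruncationSeries:
    def test_default_series_counts(self, domain_map, template):
        n = build_truncation_series(domain_map, template, "n_terminal")
        c = build_truncation_series(domain_map, template, "c_terminal")
        assert [x.name for x in n] == [f"N{i}" for i in range(1, 9)]
        assert [x.name for x in c] == [f"C{i}" for i in range(1, 6)]

    def test_interval_semantics(self, domain_map, template):
        n = build_truncation_series(domain_map, template, "n_terminal")
        assert n[0].sequence == template[DEFAULT_N_CUTS[0] - 1:]
        c = build_truncation_series(domain_map, template, "c_terminal")
        assert c[-1].sequence == template[:DEFAULT_C_CUTS[-1]]

    def test_cut_at_one_returns_full_template(self, domain_map, template):
        series = build_truncation_series(domain_map, template, "n_terminal",
                                         boundaries=[1])
        assert series[0].sequence == template

    def test_custom_two_cuts(self, domain_map, template):
        series = build_truncation_series(domain_map, template, "c_terminal",
                                         boundaries=[400, 300])
        assert [c.length for c in series] == [400, 300]

    def test_non_monotone_rejected(self, domain_map, template):
        with pytest.raises(ValueError, match="monotone|increasing"):
            build_truncation_series(domain_map, template, "n_terminal",
                                    boundaries=[45, 45])
        with pytest.raises(ValueError, match="decreasing"):
            build_truncation_series(domain_map, template, "c_terminal",
                                    boundaries=[300, 400])


class TestExtensionConstructs:
    def test_terminal_motifs(self, both_templates):
        dm, templates = both_templates
        c6, c7, c8 = build_extension_constructs(dm, templates)
        assert c6.sequence.endswith("VQIINK")
        assert c7.sequence.endswith("VQIVYK")
        assert c8.sequence.endswith("VQI")
        assert c7.spec.parent == "2N3R"

    def test_c8_contains_no_full_hexamer(self, both_templates):
        dm, templates = both_templates
        _, _, c8 = build_extension_constructs(dm, templates)
        assert "VQIVYK" not in c8.sequence
        assert "VQIINK" not in c8.sequence

    def test_length_relation(self, both_templates):
        dm, templates = both_templates
        c6, c7, c8 = build_extension_constructs(dm, templates)
        assert c6.length == c8.length + 3
        assert c6.length == c7.length

    def test_missing_2n3r_template_raises(self, both_templates):
        dm, templates = both_templates
        with pytest.raises(KeyError, match="2N3R"):
            build_extension_constructs(dm, {"2N4R": templates["2N4R"]})


class TestAmyloidogenicityRule:
    def test_recorded_outcomes_c_series_and_extensions(self, domain_map,
                                                       template):
        """The intact-hexamer rule reproduces every recorded C-series,
        extension, and isoform outcome (N-series endpoints are uncertain
        and deliberately unscored)."""
        panel = {c.name: c for c in build_all_constructs()}
        scored = [f"C{i}" for i in range(1, 9)] + \
            ["2N4R", "1N4R", "0N4R", "2N3R", "1N3R", "0N3R"]
        for name in scored:
            assert panel[name].predicted_amyloidogenic == \
                OBSERVED_OUTCOMES[name], name

    def test_vqi_alone_insufficient(self):
        assert not predict_amyloidogenic("AAAVQIAAA")
        assert predict_amyloidogenic("AAAVQIVYKAAA")
        assert predict_amyloidogenic("AAAVQIINKAAA")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_rule_equals_motif_scan(self, seq):
        """predict(s) <=> scan finds at least one hexamer occurrence."""
        modeled = ModeledSequence(sequence=seq,
                                  seq_ids=list(range(1, len(seq) + 1)))
        has_hit = bool(scan_motifs(modeled, DEFAULT_MOTIFS))
        assert predict_amyloidogenic(seq) == has_hit


class TestFasta:
    def test_round_trip(self, domain_map, template, tmp_path):
        constructs = build_isoforms(domain_map, template)
        path = tmp_path / "isoforms.fasta"
        write_fasta(constructs, path)
        records = list(SeqIO.parse(str(path), "fasta"))
        assert len(records) == 6
        by_id = {r.id: str(r.seq) for r in records}
        for c in constructs:
            assert by_id[c.name] == c.sequence

    def test_duplicate_names_rejected(self, domain_map, template, tmp_path):
        constructs = build_isoforms(domain_map, template)[:1] * 2
        with pytest.raises(ValueError, match="duplicate"):
            write_fasta(constructs, tmp_path / "dup.fasta")

    def test_empty_list_writes_empty_file(self, tmp_path, caplog):
        path = tmp_path / "empty.fasta"
        write_fasta([], path)
        assert path.read_text() == ""


def test_length_conservation_every_record():
    for c in build_all_constructs():
        expect = sum(e - s + 1 for s, e in c.spec.retained_intervals)
        expect += len(c.spec.appended_motif or "")
        assert c.length == expect, c.name
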
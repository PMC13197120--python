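import pytest

from idap.evidence_oncokb import (
    DEFAULT_LEVEL_MAP,
    OncoKBAnnotation,
    parse_annotated_maf,
    score_oncokb_drugs,
)

HEADER = "Hugo_Symbol\tHGVSp_Short\tONCOGENIC\tHIGHEST_LEVEL\tVARIANT_IN_ONCOKB\tdrugs"


def write_annotated(path, rows, header=HEADER):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestParse:
    def test_direct_parse(self, tmp_path):
        path = write_annotated(
            tmp_path / "a.tsv", ["EGFR\tp.L858R\tOncogenic\tLEVEL_1\tTrue\tErlotinib"]
        )
        (ann,) = parse_annotated_maf(path)
        assert ann.variant_in_oncokb and ann.highest_level == "LEVEL_1"
        assert ann.drugs == {"ERLOTINIB"}

    def test_negative_row_has_no_level_or_drugs(self, tmp_path):
        path = write_annotated(
            tmp_path / "a.tsv", ["XYZ\t\tUnknown\tLEVEL_1\tFalse\tErlotinib"]
        )
        (ann,) = parse_annotated_maf(path)
        assert not ann.variant_in_oncokb
        assert ann.highest_level is None and ann.drugs == frozenset()

    def test_delimiter_split(self, tmp_path):
        path = write_annotated(
            tmp_path / "a.tsv",
            ["BRAF\tp.V600E\tOncogenic\tLEVEL_1\tTrue\tDabrafenib, Trametinib"],
        )
        (ann,) = parse_annotated_maf(path)
        assert ann.drugs == {"DABRAFENIB", "TRAMETINIB"}

    def test_level_column_dialect(self, tmp_path):
        header = "ONCOGENIC\tHIGHEST_LEVEL\tVARIANT_IN_ONCOKB\tLEVEL_1\tLEVEL_3A"
        path = write_annotated(
            tmp_path / "a.tsv",
            ["Oncogenic\tLEVEL_1\tTrue\tErlotinib\tGefitinib"],
            header=header,
        )
        (ann,) = parse_annotated_maf(path)
        assert dict(ann.drug_levels) == {"ERLOTINIB": "LEVEL_1", "GEFITINIB": "LEVEL_3A"}

    def test_missing_oncokb_columns_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Hugo_Symbol\tdrugs\nEGFR\tErlotinib\n")
        with pytest.raises(ValueError, match="ONCOGENIC"):
            parse_annotated_maf(path)

    def test_lexicon_canonicalizes_drugs(self, tmp_path, toy_lexicon):
        path = write_annotated(
            tmp_path / "a.tsv", ["ABL1\tp.T315I\tOncogenic\tLEVEL_1\tTrue\tGleevec"]
        )
        (ann,) = parse_annotated_maf(path, toy_lexicon)
        assert ann.drugs == {"IMATINIB"}


def ann(drug_levels, in_db=True, level="LEVEL_1"):
    return OncoKBAnnotation(
        gene="EGFR",
        protein_change=None,
        oncogenic="Oncogenic",
        highest_level=level if in_db else None,
        variant_in_oncokb=in_db,
        drug_levels=tuple(drug_levels),
    )


class TestScore:
    def test_level1_maps_to_four(self):
        ev = score_oncokb_drugs([ann([("ERLOTINIB", "LEVEL_1")])])
        assert ev.scores["ERLOTINIB"] == DEFAULT_LEVEL_MAP["LEVEL_1"] == 4.0
        assert ev.best_level["ERLOTINIB"] == "LEVEL_1"

    def test_max_over_variant_level_pairs(self):
        # enumeration oracle: max(4, 2) = 4
        ev = score_oncokb_drugs(
            [ann([("DRUGX", "LEVEL_1")]), ann([("DRUGX", "LEVEL_3A")], level="LEVEL_3A")]
        )
        assert ev.scores["DRUGX"] == max(4.0, 2.0)
        assert ev.best_level["DRUGX"] == "LEVEL_1"

    def test_empty_annotations(self):
        assert len(score_oncokb_drugs([])) == 0

    def test_unknown_level_scores_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            ev = score_oncokb_drugs([ann([("DRUGX", "LEVEL_99")], level="LEVEL_99")])
        assert ev.scores["DRUGX"] == 0.0
        assert "unknown" in caplog.text.lower()

    def test_resistance_levels_not_positive(self):
        ev = score_oncokb_drugs([ann([("DRUGR", "LEVEL_R1")], level="LEVEL_R1")])
        assert ev.scores["DRUGR"] == 0.0

    def test_monotone_under_evidence_addition(self):
        base = [ann([("A", "LEVEL_4"), ("B", "LEVEL_2")])]
        extra = base + [ann([("A", "LEVEL_1"), ("C", "LEVEL_3B")])]
        ev_before = score_oncokb_drugs(base)
        ev_after = score_oncokb_drugs(extra)
        for drug, score in ev_before.scores.items():
            assert ev_after.scores[drug] >= score

    def test_negative_level_map_rejected(self):
        with pytest.raises(ValueError):
            score_oncokb_drugs([ann([("A", "LEVEL_1")])], {"LEVEL_1": -1.0})

    def test_invariant_no_level_when_not_in_oncokb(self):
        with pytest.raises(ValueError):
            OncoKBAnnotation(
                gene="X",
                protein_change=None,
                oncogenic="Unknown",
                highest_level="LEVEL_1",
                variant_in_oncokb=False,
                drug_levels=(),
            )
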
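import random

import pytest

from idap.evidence_kg import (
    Category,
    KGCandidate,
    KGScoreConfig,
    load_graph,
    retrieve_candidates,
    score_candidates,
)
from idap.maf_io import GeneSet

from kg_oracle import brute_force_candidates, random_toy_graph

EDGE_HEADER = "source_id\tsource_type\trelation\ttarget_id\ttarget_type"


def write_edges(path, rows):
    path.write_text(EDGE_HEADER + "\n" + "".join("\t".join(r) + "\n" for r in rows))
    return path


def gene_set(*symbols):
    return GeneSet(genes=tuple(sorted(symbols)), n_variants=max(1, len(symbols)))


TOY = [
    ("DRA", "drug", "indication", "DIS", "disease"),
    ("DRA", "drug", "drug-protein", "G1", "gene/protein"),
    ("DRB", "drug", "drug-protein", "G1", "gene/protein"),
    ("DRB", "drug", "drug-protein", "G2", "gene/protein"),
    ("DRC", "drug", "drug-protein", "G3", "gene/protein"),
    ("DIS", "disease", "off-label use", "DRD", "drug"),
]


class TestLoadGraph:
    def test_row_count(self, tmp_path):
        kg = load_graph(write_edges(tmp_path / "e.tsv", TOY[:3]))
        assert kg.n_edges == 3

    def test_duplicate_rows_collapse(self, tmp_path):
        kg = load_graph(write_edges(tmp_path / "e.tsv", [TOY[0], TOY[0]]))
        assert kg.n_edges == 1

    def test_type_conflict_names_node(self, tmp_path):
        rows = [TOY[0], ("X", "drug", "indication", "DRA", "disease")]
        with pytest.raises(ValueError, match="DRA"):
            load_graph(write_edges(tmp_path / "e.tsv", rows))

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("source_id\ttarget_id\na\tb\n")
        with pytest.raises(ValueError, match="relation"):
            load_graph(path)

    def test_names_table_attached(self, tmp_path):
        names = tmp_path / "n.tsv"
        names.write_text("id\tname\nDRA\tAlpha Drug\n")
        kg = load_graph(write_edges(tmp_path / "e.tsv", TOY), names)
        assert kg.node_name("DRA") == "Alpha Drug"
        assert kg.node_name("DRB") == "DRB"


class TestRetrieve:
    def make(self, tmp_path, rows=TOY):
        return load_graph(write_edges(tmp_path / "e.tsv", rows))

    def test_repurposing_priority_with_targets(self, tmp_path):
        cands = retrieve_candidates(
            self.make(tmp_path), "DIS", gene_set("G1", "G2"), fda={"DRB"}
        )
        by_drug = {c.drug: c for c in cands}
        assert by_drug["DRB"].category == Category.REPURPOSING_PRIORITY
        assert by_drug["DRB"].targeted_mutated_genes == {"G1", "G2"}

    def test_indication_takes_precedence(self, tmp_path):
        cands = retrieve_candidates(
            self.make(tmp_path), "DIS", gene_set("G1"), fda={"DRA"}
        )
        by_drug = {c.drug: c for c in cands}
        assert by_drug["DRA"].category == Category.CURRENT_INDICATION
        assert by_drug["DRA"].targeted_mutated_genes == {"G1"}

    def test_unapproved_target_category(self, tmp_path):
        cands = retrieve_candidates(self.make(tmp_path), "DIS", gene_set("G1"), fda=set())
        assert {c.drug: c.category for c in cands}["DRB"] == Category.TARGET_UNAPPROVED

    def test_disease_related_via_offlabel_edge(self, tmp_path):
        cands = retrieve_candidates(self.make(tmp_path), "DIS", gene_set(), fda=set())
        cats = {c.drug: c.category for c in cands}
        assert cats["DRD"] == Category.DISEASE_RELATED

    def test_empty_geneset_yields_no_target_categories(self, tmp_path):
        cands = retrieve_candidates(self.make(tmp_path), "DIS", gene_set(), fda={"DRB"})
        assert {c.category for c in cands} <= {
            Category.CURRENT_INDICATION,
            Category.DISEASE_RELATED,
        }

    def test_unknown_disease_errors(self, tmp_path):
        with pytest.raises(KeyError):
            retrieve_candidates(self.make(tmp_path), "NOPE", gene_set(), fda=set())

    def test_non_disease_node_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            retrieve_candidates(self.make(tmp_path), "DRA", gene_set(), fda=set())

    def test_category_flips_when_indication_edge_added(self, tmp_path):
        genes = gene_set("G1", "G2")
        before = retrieve_candidates(self.make(tmp_path), "DIS", genes, fda={"DRB"})
        rp = [c.drug for c in before if c.category == Category.REPURPOSING_PRIORITY]
        assert rp == ["DRB"]
        rows = TOY + [("DRB", "drug", "indication", "DIS", "disease")]
        kg2 = load_graph(write_edges(tmp_path / "e2.tsv", rows))
        after = {c.drug: c.category for c in retrieve_candidates(kg2, "DIS", genes, fda={"DRB"})}
        assert after["DRB"] == Category.CURRENT_INDICATION


class TestScore:
    def cand(self, category, n_targets, fda=True):
        return KGCandidate(
            drug="D",
            category=category,
            targeted_mutated_genes=frozenset(f"G{i}" for i in range(n_targets)),
            fda_approved=fda,
        )

    def test_default_arithmetic(self):
        (c,) = score_candidates([self.cand(Category.REPURPOSING_PRIORITY, 2)])
        assert c.txgnn_score == 100.0 + 10.0 * 1

    def test_disease_related_base(self):
        (c,) = score_candidates([self.cand(Category.DISEASE_RELATED, 0, fda=False)])
        assert c.txgnn_score == 20.0

    def test_single_target_is_base_exactly(self):
        for cat in Category:
            (c,) = score_candidates([self.cand(cat, 1)])
            assert c.txgnn_score == KGScoreConfig().base_scores[cat]

    def test_score_nondecreasing_in_targets(self):
        scores = [
            score_candidates([self.cand(Category.TARGET_UNAPPROVED, k, fda=False)])[0].txgnn_score
            for k in range(1, 6)
        ]
        assert scores == sorted(scores)

    def test_invalid_ordering_rejected(self):
        config = KGScoreConfig()
        config.base_scores[Category.DISEASE_RELATED] = 500.0
        with pytest.raises(ValueError):
            score_candidates([self.cand(Category.DISEASE_RELATED, 0)], config)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_graphs(self, tmp_path):
        """Retrieval + scoring equals an independent triple-scan on 30 random
        toy graphs (the acceptance suite runs 100)."""
        rng = random.Random(42)
        for trial in range(30):
            rows, disease, mutated, fda = random_toy_graph(rng)
            kg = load_graph(write_edges(tmp_path / f"g{trial}.tsv", rows))
            genes = GeneSet(genes=tuple(mutated), n_variants=max(1, len(mutated)))
            got = {
                c.drug: (c.category.value, c.targeted_mutated_genes, c.txgnn_score)
                for c in score_candidates(retrieve_candidates(kg, disease, genes, fda))
            }
            expected = brute_force_candidates(rows, disease, mutated, fda)
            assert got == expected, f"mismatch on trial {trial}"
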
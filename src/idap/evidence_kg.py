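"""Graph evidence: candidate retrieval and mutation-aware heuristic scoring.

The knowledge graph is a large typed biomedical graph (diseases, drugs,
genes/proteins) with relations such as ``indication`` and ``drug-protein``.
It is used as a structured resource — no neural inference. For a query
disease and a sample's mutated genes, candidates are drugs that

* treat the disease already (``indication`` edge → CURRENT_INDICATION),
* target at least one mutated gene via a ``drug-protein`` edge, partitioned
  by FDA approval into REPURPOSING_PRIORITY (approved elsewhere, not
  indicated here — the interesting repurposing class) and TARGET_UNAPPROVED,
* or touch the disease through any other disease-drug relation
  (DISEASE_RELATED).

Category precedence on overlap:
CURRENT_INDICATION > REPURPOSING_PRIORITY > TARGET_UNAPPROVED > DISEASE_RELATED.
The heuristic score is a category base plus a bonus per additional targeted
mutated gene; only the ordering of scores matters downstream because the
ranking layer percentile-normalizes within each sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

from .lexicon import DrugLexicon, normalize_name
from .maf_io import GeneSet

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("source_id", "source_type", "relation", "target_id", "target_type")

INDICATION = "indication"
DRUG_PROTEIN = "drug-protein"


class Category(str, Enum):
    REPURPOSING_PRIORITY = "REPURPOSING_PRIORITY"
    TARGET_UNAPPROVED = "TARGET_UNAPPROVED"
    CURRENT_INDICATION = "CURRENT_INDICATION"
    DISEASE_RELATED = "DISEASE_RELATED"


#: Precedence on category overlap (highest first).
CATEGORY_PRECEDENCE = (
    Category.CURRENT_INDICATION,
    Category.REPURPOSING_PRIORITY,
    Category.TARGET_UNAPPROVED,
    Category.DISEASE_RELATED,
)


@dataclass
class KGScoreConfig:
    """Category base scores and the per-extra-targeted-gene bonus.

    Defaults encode the required ordering (repurposing-priority highest;
    current-indication above broadly disease-related); exact numbers are
    immaterial after percentile normalization.
    """

    base_scores: dict[Category, float] = field(
        default_factory=lambda: {
            Category.REPURPOSING_PRIORITY: 100.0,
            Category.TARGET_UNAPPROVED: 60.0,
            Category.CURRENT_INDICATION: 40.0,
            Category.DISEASE_RELATED: 20.0,
        }
    )
    gene_bonus: float = 10.0

    def validate(self) -> None:
        b = self.base_scores
        rp = b[Category.REPURPOSING_PRIORITY]
        if not (
            rp > b[Category.TARGET_UNAPPROVED]
            and rp > b[Category.CURRENT_INDICATION] > b[Category.DISEASE_RELATED]
        ):
            raise ValueError(
                "base scores must satisfy REPURPOSING_PRIORITY > TARGET_UNAPPROVED "
                "and REPURPOSING_PRIORITY > CURRENT_INDICATION > DISEASE_RELATED"
            )
        if self.gene_bonus < 0:
            raise ValueError("gene_bonus must be >= 0")


@dataclass(frozen=True)
class KGCandidate:
    drug: str  # canonical name
    category: Category
    targeted_mutated_genes: frozenset[str]
    fda_approved: bool
    txgnn_score: float = 0.0


@dataclass
class KnowledgeGraph:
    """Typed node set plus (source, relation, target) edge triples.

    Backed by an undirected :class:`networkx.MultiGraph`: relations such as
    indication and drug-protein are queried without regard to the direction
    they were serialized in.
    """

    graph: nx.MultiGraph = field(default_factory=nx.MultiGraph)
    names: dict[str, str] = field(default_factory=dict)  # node id -> display name

    def node_type(self, node_id: str) -> str:
        return self.graph.nodes[node_id]["type"]

    def node_name(self, node_id: str) -> str:
        return self.names.get(node_id, node_id)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors_via(self, node_id: str, relation: str) -> set[str]:
        """Neighbors of *node_id* connected by *relation* (either direction)."""
        if node_id not in self.graph:
            return set()
        return {
            nbr
            for nbr, edges in self.graph.adj[node_id].items()
            if relation in edges
        }

    def relations_between(self, a: str, b: str) -> set[str]:
        if a not in self.graph or b not in self.graph.adj[a]:
            return set()
        return set(self.graph.adj[a][b])


def load_graph(
    path: str | Path, names_path: Optional[str | Path] = None
) -> KnowledgeGraph:
    """Load a TSV edge list (source_id, source_type, relation, target_id,
    target_type); duplicate edges collapse; a node typed inconsistently across
    rows is a hard error naming the node. An optional node-name TSV
    (id, name) attaches display names used for drug/gene symbol joins."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"edge list {path} lacks column(s): {', '.join(missing)}")
    kg = KnowledgeGraph()
    types: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        for node, ntype in ((row.source_id, row.source_type), (row.target_id, row.target_type)):
            prior = types.get(node)
            if prior is None:
                types[node] = ntype
            elif prior != ntype:
                raise ValueError(
                    f"node {node!r} typed {prior!r} and {ntype!r} across rows"
                )
    for node, ntype in types.items():
        kg.graph.add_node(node, type=ntype)
    for row in frame.itertuples(index=False):
        # MultiGraph keyed by relation: re-adding the same triple collapses.
        kg.graph.add_edge(row.source_id, row.target_id, key=row.relation)
    if names_path is not None:
        nframe = pd.read_csv(names_path, sep="\t", dtype=str, keep_default_na=False)
        kg.names = dict(zip(nframe["id"], nframe["name"]))
    return kg


def retrieve_candidates(
    kg: KnowledgeGraph,
    disease_id: str,
    genes: GeneSet,
    fda: set[str],
    lexicon: Optional[DrugLexicon] = None,
    disease_related_relations: Optional[Iterable[str]] = None,
) -> list[KGCandidate]:
    """Collect and categorize drug candidates for one disease and gene set.

    ``disease_related_relations`` optionally whitelists which non-indication
    disease-drug relations count as DISEASE_RELATED; by default, all do.
    Drug node ids are mapped to canonical lexicon names via the graph's name
    table; drugs absent from the lexicon keep their normalized node name with
    a warning. Candidates sharing a canonical name merge (union of targets,
    highest-precedence category).
    """
    if disease_id not in kg.graph:
        raise KeyError(f"unknown disease node {disease_id!r}")
    if kg.node_type(disease_id) != "disease":
        raise ValueError(f"node {disease_id!r} is not typed 'disease'")
    related_whitelist = (
        set(disease_related_relations) if disease_related_relations is not None else None
    )

    def canonical_drug(node_id: str) -> str:
        raw = kg.node_name(node_id)
        if lexicon is not None:
            if raw not in lexicon:
                logger.warning("drug node %r (%r) not in lexicon; keeping name", node_id, raw)
            return lexicon.canonicalize(raw)
        return normalize_name(raw)

    gene_symbols = set(genes.genes)

    def symbol(node_id: str) -> str:
        return normalize_name(kg.node_name(node_id))

    indication_drugs = {
        n for n in kg.neighbors_via(disease_id, INDICATION) if kg.node_type(n) == "drug"
    }
    # drug -> mutated gene symbols it targets
    targets: dict[str, set[str]] = {}
    for node, data in kg.graph.nodes(data=True):
        if data["type"] != "drug":
            continue
        hit = {
            symbol(nbr)
            for nbr in kg.neighbors_via(node, DRUG_PROTEIN)
            if kg.node_type(nbr) == "gene/protein" and symbol(nbr) in gene_symbols
        }
        if hit:
            targets[node] = hit
    disease_related = set()
    for nbr in kg.graph.adj[disease_id]:
        if kg.node_type(nbr) != "drug":
            continue
        rels = kg.relations_between(disease_id, nbr) - {INDICATION}
        if related_whitelist is not None:
            rels &= related_whitelist
        if rels:
            disease_related.add(nbr)

    merged: dict[str, dict] = {}
    order = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}

    def add(node: str, category: Category) -> None:
        name = canonical_drug(node)
        entry = merged.setdefault(
            name,
            {"category": category, "targets": set(), "fda": False},
        )
        if order[category] < order[entry["category"]]:
            entry["category"] = category
        entry["targets"] |= targets.get(node, set())
        entry["fda"] = entry["fda"] or name in fda

    for node in indication_drugs:
        add(node, Category.CURRENT_INDICATION)
    for node in targets:
        if node in indication_drugs:
            continue
        name = canonical_drug(node)
        cat = (
            Category.REPURPOSING_PRIORITY
            if name in fda
            else Category.TARGET_UNAPPROVED
        )
        add(node, cat)
    for node in disease_related - indication_drugs - set(targets):
        add(node, Category.DISEASE_RELATED)

    return [
        KGCandidate(
            drug=name,
            category=entry["category"],
            targeted_mutated_genes=frozenset(entry["targets"]),
            fda_approved=entry["fda"],
        )
        for name, entry in sorted(merged.items())
    ]


def score_candidates(
    candidates: Iterable[KGCandidate],
    config: Optional[KGScoreConfig] = None,
) -> list[KGCandidate]:
    """Assign ``txgnn_score = base(category) + bonus * max(0, n_targets - 1)``."""
    if config is None:
        config = KGScoreConfig()
    config.validate()
    scored = []
    for cand in candidates:
        extra = max(0, len(cand.targeted_mutated_genes) - 1)
        score = config.base_scores[cand.category] + config.gene_bonus * extra
        scored.append(replace(cand, txgnn_score=score))
    return scored
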
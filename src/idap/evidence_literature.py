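"""Literature evidence: query construction and gene-drug mention counting.

Abstracts are retrieved per altered gene with the query template
``"<cancer type> AND <gene> AND (therapy OR treatment OR inhibitor)"`` and
scanned for drug names from the shared lexicon. The layer is evidence
retrieval, not causal inference: a co-mention says the drug and gene appear
in the same treatment-related abstract, nothing more.

Mentions are counted per distinct abstract by default — repeated mentions
within one abstract are not independent evidence — with a per-occurrence mode
available. Abstract identifiers are retained in a provenance table even
though the merged output exposes only counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .lexicon import DrugLexicon, count_occurrences, match_mentions, normalize_name
from .maf_io import GeneSet

QUERY_TEMPLATE = "{cancer_type} AND {gene} AND (therapy OR treatment OR inhibitor)"

_WS_COLLAPSE = " ".join


@dataclass(frozen=True)
class AbstractRecord:
    """One retrieved abstract, keyed by the gene it was retrieved for."""

    gene_query: str
    abstract_id: str
    text: str


@dataclass
class MentionCounts:
    """Gene-drug mention counts plus per-drug totals and provenance."""

    per_gene_drug: dict[tuple[str, str], int] = field(default_factory=dict)
    provenance: list[tuple[str, str, str]] = field(default_factory=list)  # (gene, drug, abstract_id)

    @property
    def totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_, drug), n in self.per_gene_drug.items():
            out[drug] = out.get(drug, 0) + n
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "drug": d, "mention_count": n}
            for (g, d), n in sorted(self.per_gene_drug.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "drug", "mention_count"])


def build_query(cancer_type: str, gene: str) -> str:
    """The exact retrieval query for one cancer type and gene."""
    cancer_type = _WS_COLLAPSE(cancer_type.split())
    gene = _WS_COLLAPSE(gene.split())
    if not cancer_type or not gene:
        raise ValueError("cancer_type and gene must be non-empty")
    return QUERY_TEMPLATE.format(cancer_type=cancer_type, gene=gene)


def count_mentions(
    corpus: Iterable[AbstractRecord],
    genes: GeneSet,
    lexicon: DrugLexicon,
    per_occurrence: bool = False,
) -> MentionCounts:
    """Aggregate abstract-level drug matches into gene-drug counts.

    ``mention_count(g, d)`` is the number of distinct abstracts retrieved for
    gene *g* whose text mentions drug *d* (or total occurrences across those
    abstracts with ``per_occurrence=True``). Abstracts retrieved for genes
    outside the sample's gene set are ignored. Counts are invariant to
    abstract ordering and duplicated abstract ids.
    """
    gene_members = set(genes.genes)
    seen: dict[tuple[str, str], set[str]] = {}
    occ: dict[tuple[str, str], int] = {}
    provenance: list[tuple[str, str, str]] = []
    for record in corpus:
        gene = normalize_name(record.gene_query)
        if gene not in gene_members:
            continue
        if per_occurrence:
            for drug, n in count_occurrences(record.text, lexicon).items():
                key = (gene, drug)
                if record.abstract_id not in seen.setdefault(key, set()):
                    seen[key].add(record.abstract_id)
                    occ[key] = occ.get(key, 0) + n
                    provenance.append((gene, drug, record.abstract_id))
        else:
            for drug in match_mentions(record.text, lexicon):
                key = (gene, drug)
                if record.abstract_id not in seen.setdefault(key, set()):
                    seen[key].add(record.abstract_id)
                    provenance.append((gene, drug, record.abstract_id))
    counts = MentionCounts(provenance=sorted(provenance))
    if per_occurrence:
        counts.per_gene_drug = dict(sorted(occ.items()))
    else:
        counts.per_gene_drug = {k: len(ids) for k, ids in sorted(seen.items())}
    return counts


def read_corpus(path: str | Path) -> list[AbstractRecord]:
    """Read a JSON-lines abstract corpus (keys gene_query, abstract_id, text)."""
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        records.append(
            AbstractRecord(
                gene_query=str(obj["gene_query"]),
                abstract_id=str(obj["abstract_id"]),
                text=str(obj["text"]),
            )
        )
    return records
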
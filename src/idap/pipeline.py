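"""Offline pipeline orchestration: MAF → evidence layers → ranked report.

``run_pipeline`` wires the modules together over a local evidence bundle (a
directory of the standard input files). Online fetching lives in
:mod:`idap.adapters` and writes the same file formats, so the core pipeline
is identical either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import evidence_kg, evidence_literature, evidence_oncokb, evidence_trials
from .evidence_trials import TrialRecord
from .fixtures import BUNDLE_FILES
from .integrate_rank import WeightConfig, merge_and_rank
from .lexicon import (
    DrugLexicon,
    build_lexicon,
    normalize_name,
    read_fda_list,
    read_source_table,
)
from .maf_io import extract_genes, read_maf
from .report import PatientReport, build_report, render

logger = logging.getLogger(__name__)

REQUIRED_BUNDLE_ROLES = ("kg_edges", "fda", "drug_sources", "abstracts", "trials", "oncokb")
OPTIONAL_BUNDLE_ROLES = ("kg_names", "disease_map", "truth")


@dataclass
class RunConfig:
    """One pipeline invocation: sample inputs, bundle paths, scoring knobs."""

    cancer_type: str
    maf_path: Path
    bundle_dir: Path
    out_dir: Path
    weights: WeightConfig = field(default_factory=WeightConfig)
    kg_scores: evidence_kg.KGScoreConfig = field(default_factory=evidence_kg.KGScoreConfig)
    oncokb_level_map: Optional[dict[str, float]] = None
    top_k: int = 20
    deterministic: bool = True


@dataclass
class RunResult:
    ranked: pd.DataFrame
    report: PatientReport
    paths: dict[str, Path]


def bundle_paths(bundle_dir: Path) -> dict[str, Path]:
    """Resolve bundle role → file path; missing required files are an error
    naming the file."""
    paths = {role: bundle_dir / fname for role, fname in BUNDLE_FILES.items()}
    for role in REQUIRED_BUNDLE_ROLES:
        if not paths[role].exists():
            raise FileNotFoundError(f"evidence bundle is missing {paths[role]}")
    return paths


def resolve_disease_id(
    cancer_type: str, kg: evidence_kg.KnowledgeGraph, disease_map_path: Optional[Path]
) -> str:
    """Ground the cancer-type string to a disease node id.

    A user-supplied two-column map (cancer_type, disease_id) takes priority;
    otherwise fall back to exact match of the normalized cancer type against
    disease node names or ids.
    """
    wanted = normalize_name(cancer_type)
    if disease_map_path is not None and disease_map_path.exists():
        frame = pd.read_csv(disease_map_path, sep="\t", dtype=str, keep_default_na=False)
        for row in frame.itertuples(index=False):
            if normalize_name(row.cancer_type) == wanted:
                return row.disease_id
    for node, data in kg.graph.nodes(data=True):
        if data.get("type") == "disease" and normalize_name(kg.node_name(node)) == wanted:
            return node
    raise KeyError(f"cannot resolve cancer type {cancer_type!r} to a disease node")


def _canonical_trials(records: list[TrialRecord], lexicon: DrugLexicon) -> list[TrialRecord]:
    return [
        TrialRecord(
            drug=lexicon.canonicalize(r.drug),
            nct_id=r.nct_id,
            title=r.title,
            condition=r.condition,
            phase=r.phase,
            status=r.status,
        )
        for r in records
    ]


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full offline pipeline and write the report files."""
    paths = bundle_paths(config.bundle_dir)

    variants = read_maf(config.maf_path)
    genes = extract_genes(variants)
    logger.info("sample: %d variants, %d altered genes", genes.n_variants, len(genes))

    lexicon = build_lexicon(read_source_table(paths["drug_sources"]))
    fda = {lexicon.canonicalize(n) for n in read_fda_list(paths["fda"])}

    annotations = evidence_oncokb.parse_annotated_maf(paths["oncokb"], lexicon)
    oncokb = evidence_oncokb.score_oncokb_drugs(annotations, config.oncokb_level_map)

    corpus = evidence_literature.read_corpus(paths["abstracts"])
    mentions = evidence_literature.count_mentions(corpus, genes, lexicon)

    kg = evidence_kg.load_graph(
        paths["kg_edges"],
        paths["kg_names"] if paths["kg_names"].exists() else None,
    )
    disease_id = resolve_disease_id(
        config.cancer_type, kg, paths.get("disease_map")
    )
    candidates = evidence_kg.retrieve_candidates(kg, disease_id, genes, fda, lexicon)
    candidates = evidence_kg.score_candidates(candidates, config.kg_scores)

    trial_records = _canonical_trials(
        evidence_trials.read_trial_records(paths["trials"]), lexicon
    )
    trials = evidence_trials.summarize_trials(trial_records)

    ranked = merge_and_rank(oncokb, mentions, candidates, trials, config.weights)
    report = build_report(
        config.cancer_type, genes, variants, ranked, candidates, config.top_k
    )
    out_paths = render(report, config.out_dir, deterministic=config.deterministic)
    return RunResult(ranked=ranked, report=report, paths=out_paths)


def read_truth_set(path: str | Path, lexicon: Optional[DrugLexicon] = None) -> set[str]:
    """Read a (drug, gene, disease) truth table into a canonical drug set."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "drug" not in frame.columns:
        raise ValueError(f"truth set {path} lacks required column 'drug'")
    if lexicon is not None:
        return {lexicon.canonicalize(d) for d in frame["drug"] if d.strip()}
    return {normalize_name(d) for d in frame["drug"] if d.strip()}
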
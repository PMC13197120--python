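"""Patient-level report: ranked table, top-20 bar data, gene-drug network.

The report combines the sample summary (cancer type, variant count, altered
genes), the variant table, the ranked drug table with all evidence layers,
bar data for the top min(20, N) drugs by combined score, and a
cancer-gene-drug network whose edges are the gene-drug associations from the
graph module plus one cancer-gene edge per displayed mutated gene.

Output is a self-contained HTML document (tables plus an inline SVG bar
chart) with TSV side files. Rendering is deterministic by default —
timestamps suppressed — so repeated renders of the same input are
byte-identical.
"""

from __future__ import annotations

import datetime
import html
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .evidence_kg import KGCandidate
from .maf_io import GeneSet, MafVariant, variants_to_frame

NETWORK_COLUMNS = ["source", "target", "edge_type"]


@dataclass
class PatientReport:
    cancer_type: str
    n_variants: int
    genes: tuple[str, ...]
    ranked: pd.DataFrame
    bar_data: list[tuple[str, float]] = field(default_factory=list)
    network_nodes: list[tuple[str, str]] = field(default_factory=list)  # (id, type)
    network_edges: list[tuple[str, str, str]] = field(default_factory=list)
    variants: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_report(
    cancer_type: str,
    gene_set: GeneSet,
    variants: Sequence[MafVariant],
    ranked: pd.DataFrame,
    kg_candidates: Sequence[KGCandidate],
    top_k: int = 20,
) -> PatientReport:
    """Assemble the report object from the ranked table and KG candidates.

    ``bar_data`` is the top min(top_k, N) prefix of the ranking. The network
    shows the displayed drugs, the mutated genes they target, one gene-drug
    edge per targeting relation and one cancer-gene edge per displayed gene.
    """
    top = ranked.head(top_k)
    bar_data = [(str(r.drug), float(r.combined_score)) for r in top.itertuples()]
    displayed = set(top["drug"]) if len(top) else set()
    targets_by_drug = {
        c.drug: sorted(c.targeted_mutated_genes)
        for c in kg_candidates
        if c.drug in displayed
    }
    shown_genes = sorted({g for genes in targets_by_drug.values() for g in genes})
    nodes: list[tuple[str, str]] = [(cancer_type, "cancer")]
    nodes += [(g, "gene") for g in shown_genes]
    nodes += [(d, "drug") for d in sorted(displayed)]
    edges: list[tuple[str, str, str]] = [
        (cancer_type, g, "cancer-gene") for g in shown_genes
    ]
    for drug in sorted(targets_by_drug):
        for gene in targets_by_drug[drug]:
            edges.append((gene, drug, "gene-drug"))
    return PatientReport(
        cancer_type=cancer_type,
        n_variants=gene_set.n_variants,
        genes=gene_set.genes,
        ranked=ranked,
        bar_data=bar_data,
        network_nodes=nodes,
        network_edges=edges,
        variants=variants_to_frame(variants),
    )


def _svg_bar_chart(bar_data: list[tuple[str, float]], width: int = 640) -> str:
    if not bar_data:
        return ""
    bar_h, gap, label_w = 18, 6, 180
    height = len(bar_data) * (bar_h + gap) + gap
    vmax = max(score for _, score in bar_data) or 1.0
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'font-family="sans-serif" font-size="12">'
    ]
    for i, (drug, score) in enumerate(bar_data):
        y = gap + i * (bar_h + gap)
        w = (width - label_w - 80) * score / vmax
        parts.append(
            f'<text x="{label_w - 6}" y="{y + bar_h - 4}" text-anchor="end">'
            f"{html.escape(drug)}</text>"
            f'<rect x="{label_w}" y="{y}" width="{w:.1f}" height="{bar_h}" fill="#4c72b0"/>'
            f'<text x="{label_w + w + 4:.1f}" y="{y + bar_h - 4}">{score:.3f}</text>'
        )
    parts.append("</svg>")
    return "".join(parts)


def _html_table(frame: pd.DataFrame, float_format: str = "{:.6g}") -> str:
    if frame.empty:
        return "<p><em>none</em></p>"
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in frame.columns)
    body = []
    for row in frame.itertuples(index=False):
        cells = []
        for value in row:
            if isinstance(value, float):
                cells.append(f"<td>{float_format.format(value)}</td>")
            else:
                cells.append(f"<td>{html.escape(str(value))}</td>")
        body.append("<tr>" + "".join(cells) + "</tr>")
    return (
        '<table border="1" cellspacing="0" cellpadding="3">'
        f"<thead><tr>{head}</tr></thead><tbody>{''.join(body)}</tbody></table>"
    )


def render(
    report: PatientReport,
    out_dir: str | Path,
    deterministic: bool = True,
) -> dict[str, Path]:
    """Write report.html plus TSV side files; returns the paths written."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create report directory {out}: {exc}") from exc

    paths = {
        "report": out / "report.html",
        "ranked": out / "ranked_drugs.tsv",
        "variants": out / "variants.tsv",
        "network": out / "network_edges.tsv",
    }
    report.ranked.to_csv(paths["ranked"], sep="\t", index=False, lineterminator="\n")
    report.variants.to_csv(paths["variants"], sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(report.network_edges, columns=NETWORK_COLUMNS).to_csv(
        paths["network"], sep="\t", index=False, lineterminator="\n"
    )

    stamp = (
        ""
        if deterministic
        else f"<p>Generated {datetime.datetime.now().isoformat(timespec='seconds')}</p>"
    )
    if len(report.ranked):
        candidates_html = (
            f"<h2>Top {len(report.bar_data)} candidates by combined score</h2>"
            + _svg_bar_chart(report.bar_data)
            + "<h2>Ranked therapeutic hypotheses</h2>"
            + _html_table(report.ranked)
        )
    else:
        candidates_html = (
            "<h2>Candidates</h2><p><strong>No candidates:</strong> no evidence "
            "layer returned a drug for this sample.</p>"
        )
    network_html = _html_table(
        pd.DataFrame(report.network_edges, columns=NETWORK_COLUMNS)
    )
    doc = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>IDAP report — {html.escape(report.cancer_type)}</title></head>
<body>
<h1>Integrated drug annotation report</h1>
{stamp}
<h2>Sample summary</h2>
<ul>
<li>Cancer type: {html.escape(report.cancer_type)}</li>
<li>Variants detected: {report.n_variants}</li>
<li>Altered genes ({len(report.genes)}): {html.escape(', '.join(report.genes))}</li>
</ul>
{candidates_html}
<h2>Cancer-gene-drug network</h2>
{network_html}
<h2>Variants</h2>
{_html_table(report.variants)}
<p><small>Scores integrate graph, literature and curated evidence as
within-sample percentiles with fixed bonuses for multi-source support,
curated evidence and trial linkage. Variant-level curated categories are
joined to drugs by gene. Outputs are prioritized hypotheses for expert
review, not treatment recommendations.</small></p>
</body></html>
"""
    paths["report"].write_text(doc)
    return paths
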
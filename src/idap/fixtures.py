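"""Deterministic synthetic evidence bundles with known expected output.

The generator writes every input format the pipeline consumes — a MAF, a
knowledge-graph edge list with node names, an FDA-approved list, drug-name
source tables, a JSON-lines abstract corpus, trial records, an
OncoKB-annotator-style TSV, a disease-name map and a truth set — and, next
to them, the ranked candidate table the pipeline is expected to produce.

That expectation is computed by a deliberately naive, loop-based reference
implementation embedded here (``naive_oracle_ranked``) which shares no code
with the pipeline modules: two independent implementations of the same
rules cross-validate each other. Same seed ⇒ byte-identical files.

The generated cohort emulates one tumor sample of a named cancer type with a
handful of altered driver genes and a few dozen candidate drugs spread over
the four evidence layers, at roughly the evidence sparsity the method is
designed for (most drugs supported by a single layer, a minority curated).
It does not emulate realistic mutation spectra or cohort-scale variation.
"""

from __future__ import annotations

import hashlib
import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

GENE_POOL = [
    "TP53", "KRAS", "EGFR", "BRAF", "PIK3CA", "PTEN", "APC", "RB1",
    "ALK", "MET", "ERBB2", "BRCA1", "BRCA2", "NRAS", "IDH1", "CDKN2A",
    "SMAD4", "STK11", "KEAP1", "ATM",
]
DECOY_GENES = ["GAPDH", "ACTB", "MYH7", "TTN"]

_PREFIXES = [
    "VELA", "TORI", "NILO", "SORA", "PALBO", "LENVA", "CAPE", "GEFI",
    "LORLA", "TRAME", "DABRA", "OSIME", "RUXO", "ALPE", "NERA", "SELU",
    "TEMO", "VINO", "DOCE", "PEMET", "CRIZO", "ENTRE", "BINI", "IBRU",
    "ACALA", "DUVE", "UMBRA", "ZANU", "PIRTO", "FOSTA",
]
_SUFFIXES = ["TINIB", "CLIB", "MUMAB", "LIMUS", "RABINE", "TECAN", "PARIB", "SERTIB"]

VARIANT_CLASSES = [
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "In_Frame_Ins", "Splice_Site", "Silent",
]
ONCOKB_LEVELS = ["LEVEL_1", "LEVEL_2", "LEVEL_3A", "LEVEL_3B", "LEVEL_4"]
PHASES = ["PHASE1", "PHASE2", "PHASE3", "PHASE4", "PHASE2|PHASE3", "NA"]
STATUSES = ["RECRUITING", "COMPLETED", "ACTIVE_NOT_RECRUITING", "TERMINATED"]

BUNDLE_FILES = {
    "maf": "sample.maf",
    "oncokb": "oncokb_annotated.maf",
    "kg_edges": "kg_edges.tsv",
    "kg_names": "kg_node_names.tsv",
    "fda": "fda_approved.txt",
    "drug_sources": "drug_sources.tsv",
    "abstracts": "abstracts.jsonl",
    "trials": "trials.tsv",
    "disease_map": "disease_map.tsv",
    "truth": "truth_set.tsv",
    "expected": "expected_ranked.tsv",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of the synthetic cohort. Same seed ⇒ byte-identical files."""

    seed: int = 7
    cancer_type: str = "lung cancer"
    n_genes: int = 8
    n_drugs: int = 24
    n_abstracts_per_gene: int = 5
    max_trials_per_drug: int = 4
    oncokb_fraction: float = 0.25
    trial_fraction: float = 0.7
    fda_fraction: float = 0.6
    alias_fraction: float = 0.3
    indication_fraction: float = 0.15
    target_edge_fraction: float = 0.45
    offlabel_fraction: float = 0.15


# ---------------------------------------------------------------------------
# generation


def _make_drug_names(rng: random.Random, n: int) -> list[str]:
    names: list[str] = []
    seen = set()
    while len(names) < n:
        name = rng.choice(_PREFIXES) + rng.choice(_SUFFIXES)
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _write(path: Path, text: str) -> None:
    path.write_text(text)


def make_toy_cohort(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Generate a full offline evidence bundle plus its expected ranking.

    Returns (and writes as ``manifest.json``) a manifest mapping file roles
    to paths and SHA-256 hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    genes = sorted(rng.sample(GENE_POOL, spec.n_genes))
    drugs = _make_drug_names(rng, spec.n_drugs)
    aliases = {
        d: "ALI" + d
        for d in drugs
        if rng.random() < spec.alias_fraction
    }

    # --- drug source tables (two overlapping sources) and FDA list
    src_rows = []
    for i, d in enumerate(drugs):
        title = d.title()
        src_rows.append((title, aliases.get(d, "")))
        if i % 3 == 0:  # second source re-lists a third of the drugs
            src_rows.append((d.lower(), ""))
    src_text = "name\taliases\n" + "".join(
        f"{name}\t{alias}\n" for name, alias in src_rows
    )
    _write(out / BUNDLE_FILES["drug_sources"], src_text)

    fda = sorted(d for d in drugs if rng.random() < spec.fda_fraction)
    _write(out / BUNDLE_FILES["fda"], "".join(f"{d.title()}\n" for d in fda))

    # --- MAF (with a comment pragma and one intergenic row)
    maf_rows = []
    sample_id = f"SAMPLE_{spec.seed:04d}"
    pos = 1000
    for g in genes:
        for _ in range(rng.randint(1, 3)):
            pos += rng.randint(100, 5000)
            maf_rows.append(
                (
                    g if rng.random() < 0.8 else g.lower(),
                    str(rng.randint(1, 22)),
                    str(pos),
                    rng.choice("ACGT"),
                    rng.choice("ACGT"),
                    rng.choice(VARIANT_CLASSES),
                    f"p.X{rng.randint(1, 500)}Y",
                    sample_id,
                )
            )
    header = (
        "Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
        "Tumor_Seq_Allele2\tVariant_Classification\tHGVSp_Short\tTumor_Sample_Barcode"
    )
    intergenic = ("", "1", "500", "A", "T", "IGR", "", sample_id)
    maf_text = "#version 2.4\n" + header + "\n" + "".join(
        "\t".join(r) + "\n" for r in maf_rows + [intergenic]
    )
    _write(out / BUNDLE_FILES["maf"], maf_text)

    # --- knowledge graph
    disease_id = "disease:query"
    other_disease = "disease:other"
    edges: list[tuple[str, str, str, str, str]] = []
    names: dict[str, str] = {disease_id: spec.cancer_type, other_disease: "other disease"}
    for g in genes + DECOY_GENES:
        names[f"gene:{g}"] = g
    for d in drugs:
        names[f"drug:{d}"] = d.title()

    def edge(src, stype, rel, tgt, ttype):
        edges.append((src, stype, rel, tgt, ttype))

    # anchor both disease nodes so they exist even in sparse graphs
    edge(disease_id, "disease", "parent-child", other_disease, "disease")
    for d in drugs:
        node = f"drug:{d}"
        if rng.random() < spec.indication_fraction:
            edge(node, "drug", "indication", disease_id, "disease")
        if rng.random() < 0.3:
            edge(node, "drug", "indication", other_disease, "disease")
        for g in genes:
            if rng.random() < spec.target_edge_fraction / len(genes) * 3:
                edge(node, "drug", "drug-protein", f"gene:{g}", "gene/protein")
        if rng.random() < 0.2:
            edge(node, "drug", "drug-protein", f"gene:{rng.choice(DECOY_GENES)}", "gene/protein")
        if rng.random() < spec.offlabel_fraction:
            edge(disease_id, "disease", "off-label use", node, "drug")
    # duplicate a row to exercise edge dedup
    if edges:
        edges.append(edges[0])
    kg_text = "source_id\tsource_type\trelation\ttarget_id\ttarget_type\n" + "".join(
        "\t".join(e) + "\n" for e in edges
    )
    _write(out / BUNDLE_FILES["kg_edges"], kg_text)
    _write(
        out / BUNDLE_FILES["kg_names"],
        "id\tname\n" + "".join(f"{i}\t{n}\n" for i, n in sorted(names.items())),
    )
    _write(
        out / BUNDLE_FILES["disease_map"],
        f"cancer_type\tdisease_id\n{spec.cancer_type}\t{disease_id}\n",
    )

    # --- abstract corpus
    abstract_rows = []
    pmid = 10_000_000
    for g in genes:
        for _ in range(spec.n_abstracts_per_gene):
            pmid += rng.randint(1, 9)
            k = rng.randint(0, min(3, len(drugs)))
            mentioned = rng.sample(drugs, k)
            words = []
            for d in mentioned:
                token = aliases[d].lower() if d in aliases and rng.random() < 0.5 else d.lower()
                words.append(f"treatment with {token}")
            text = (
                f"In {spec.cancer_type}, {g} alterations were studied. "
                + "; ".join(words)
                + (" showed activity." if words else "No drug discussed.")
            )
            abstract_rows.append(
                {"gene_query": g, "abstract_id": f"PMID{pmid}", "text": text}
            )
    _write(
        out / BUNDLE_FILES["abstracts"],
        "".join(json.dumps(r, sort_keys=True) + "\n" for r in abstract_rows),
    )

    # --- OncoKB-annotated MAF (single drugs-column dialect)
    ok_header = "Hugo_Symbol\tHGVSp_Short\tONCOGENIC\tHIGHEST_LEVEL\tVARIANT_IN_ONCOKB\tdrugs"
    ok_rows = []
    for r in maf_rows:
        gene = r[0].upper()
        if rng.random() < spec.oncokb_fraction:
            level = rng.choice(ONCOKB_LEVELS)
            ok_drugs = ", ".join(
                x.title() for x in rng.sample(drugs, min(len(drugs), rng.randint(1, 2)))
            )
            ok_rows.append((gene, r[6], "Oncogenic", level, "True", ok_drugs))
        else:
            ok_rows.append((gene, r[6], "Unknown", "", "False", ""))
    _write(
        out / BUNDLE_FILES["oncokb"],
        ok_header + "\n" + "".join("\t".join(r) + "\n" for r in ok_rows),
    )

    # --- trial records
    trial_rows = []
    nct = 10_000
    for d in drugs:
        if rng.random() < spec.trial_fraction:
            for _ in range(rng.randint(1, spec.max_trials_per_drug)):
                nct += rng.randint(1, 50)
                trial_rows.append(
                    (
                        d.title(),
                        f"NCT{nct:08d}",
                        f"A study of {d.title()} in {spec.cancer_type}",
                        spec.cancer_type,
                        rng.choice(PHASES),
                        rng.choice(STATUSES),
                    )
                )
    if trial_rows:  # duplicated row exercises unique-NCT counting
        trial_rows.append(trial_rows[0])
    _write(
        out / BUNDLE_FILES["trials"],
        "drug\tnct_id\ttitle\tcondition\tphase\tstatus\n"
        + "".join("\t".join(r) + "\n" for r in trial_rows),
    )

    # --- expected output via the embedded naive oracle
    expected = naive_oracle_ranked(
        maf_rows=maf_rows,
        src_rows=src_rows,
        fda_titles=[d.title() for d in fda],
        kg_edges=edges,
        kg_names=names,
        disease_id=disease_id,
        abstracts=abstract_rows,
        oncokb_rows=ok_rows,
        trial_rows=trial_rows,
    )
    expected.to_csv(out / BUNDLE_FILES["expected"], sep="\t", index=False, lineterminator="\n")

    # --- truth set: a few drugs drawn from the expected ranking
    truth = sorted(
        rng.sample(list(expected["drug"]), min(3, len(expected)))
    ) if len(expected) else []
    _write(
        out / BUNDLE_FILES["truth"],
        "drug\tgene\tdisease\n"
        + "".join(f"{t}\t{rng.choice(genes)}\t{spec.cancer_type}\n" for t in truth),
    )

    manifest = {
        "seed": spec.seed,
        "cancer_type": spec.cancer_type,
        "genes": genes,
        "files": {
            role: {
                "path": fname,
                "sha256": hashlib.sha256((out / fname).read_bytes()).hexdigest(),
            }
            for role, fname in BUNDLE_FILES.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# naive reference oracle (independent of the pipeline modules)


def _oracle_normalize(s: str) -> str:
    return re.sub(r"\s+", " ", s.strip()).upper()


def naive_oracle_ranked(
    maf_rows,
    src_rows,
    fda_titles,
    kg_edges,
    kg_names,
    disease_id,
    abstracts,
    oncokb_rows,
    trial_rows,
) -> pd.DataFrame:
    """Loop-based transcription of the ranking rules, for cross-validation.

    Re-derives every layer from the raw generated rows with plain loops and
    literal constants; shares nothing with the pipeline modules.
    """
    # lexicon: name/alias -> canonical (first seen wins)
    alias_map: dict[str, str] = {}
    for name, alias_cell in src_rows:
        canon = _oracle_normalize(name)
        if canon and canon not in alias_map:
            alias_map[canon] = canon
        for a in alias_cell.split(";"):
            a = _oracle_normalize(a)
            if a and a not in alias_map:
                alias_map[a] = alias_map.get(_oracle_normalize(name), _oracle_normalize(name))

    genes = sorted({_oracle_normalize(r[0]) for r in maf_rows if r[0].strip()})
    fda = {_oracle_normalize(t) for t in fda_titles}

    # --- oncokb layer: max mapped level per drug
    level_values = {"LEVEL_1": 4.0, "LEVEL_2": 3.0, "LEVEL_3A": 2.0, "LEVEL_3B": 1.5, "LEVEL_4": 1.0}
    ok_scores: dict[str, float] = {}
    for _, _, _, level, in_db, drug_cell in oncokb_rows:
        if in_db != "True":
            continue
        for raw in drug_cell.split(","):
            raw = raw.strip()
            if not raw:
                continue
            d = alias_map.get(_oracle_normalize(raw), _oracle_normalize(raw))
            v = level_values.get(level, 0.0)
            if d not in ok_scores or v > ok_scores[d]:
                ok_scores[d] = v

    # --- literature layer: distinct abstracts per (gene, drug), token match
    per_pair: dict[tuple[str, str], set[str]] = {}
    for rec in abstracts:
        g = _oracle_normalize(rec["gene_query"])
        if g not in genes:
            continue
        tokens = [t for t in re.split(r"[^A-Z0-9]+", _oracle_normalize(rec["text"])) if t]
        for entry, canon in alias_map.items():
            # single-token names only in generated fixtures
            if entry in tokens:
                per_pair.setdefault((g, canon), set()).add(rec["abstract_id"])
    pm_totals: dict[str, int] = {}
    for (_, d), ids in per_pair.items():
        pm_totals[d] = pm_totals.get(d, 0) + len(ids)

    # --- kg layer: brute-force triple scan
    triples = {(s, rel, t) for s, _, rel, t, _ in kg_edges}
    node_type: dict[str, str] = {}
    for s, st, _, t, tt in kg_edges:
        node_type[s] = st
        node_type[t] = tt

    def drug_name(node):
        raw = _oracle_normalize(kg_names.get(node, node))
        return alias_map.get(raw, raw)

    drug_nodes = sorted(n for n, ty in node_type.items() if ty == "drug")
    indication = set()
    targets: dict[str, set[str]] = {}
    related = set()
    for node in drug_nodes:
        for s, rel, t in triples:
            a, b = (s, t) if s == node else (t, s) if t == node else (None, None)
            if a is None:
                continue
            if rel == "indication" and b == disease_id:
                indication.add(node)
            if rel == "drug-protein" and node_type.get(b) == "gene/protein":
                sym = _oracle_normalize(kg_names.get(b, b))
                if sym in genes:
                    targets.setdefault(node, set()).add(sym)
            if rel not in ("indication",) and b == disease_id and node_type.get(b) == "disease":
                related.add(node)
    merged: dict[str, dict] = {}
    precedence = {"CURRENT_INDICATION": 0, "REPURPOSING_PRIORITY": 1, "TARGET_UNAPPROVED": 2, "DISEASE_RELATED": 3}
    for node in drug_nodes:
        name = drug_name(node)
        cat = None
        if node in indication:
            cat = "CURRENT_INDICATION"
        elif node in targets:
            cat = "REPURPOSING_PRIORITY" if name in fda else "TARGET_UNAPPROVED"
        elif node in related:
            cat = "DISEASE_RELATED"
        if cat is None:
            continue
        entry = merged.setdefault(name, {"cat": cat, "targets": set()})
        if precedence[cat] < precedence[entry["cat"]]:
            entry["cat"] = cat
        entry["targets"] |= targets.get(node, set())
    base = {"REPURPOSING_PRIORITY": 100.0, "TARGET_UNAPPROVED": 60.0, "CURRENT_INDICATION": 40.0, "DISEASE_RELATED": 20.0}
    tx_scores = {
        name: base[e["cat"]] + 10.0 * max(0, len(e["targets"]) - 1)
        for name, e in merged.items()
    }

    # --- trials layer
    phase_value = {"PHASE1": 1, "PHASE2": 2, "PHASE3": 3, "PHASE4": 4}

    def prio(phase):
        return max((phase_value.get(p.strip().upper(), 0) for p in phase.split("|")), default=0)

    trials_by_drug: dict[str, list[tuple]] = {}
    for drug, nct_id, title, _, phase, _ in trial_rows:
        d = alias_map.get(_oracle_normalize(drug), _oracle_normalize(drug))
        trials_by_drug.setdefault(d, []).append((nct_id, phase, title))
    summaries = {}
    for d, rows in trials_by_drug.items():
        n = len({r[0] for r in rows})
        top = sorted(rows, key=lambda r: (-prio(r[1]), r[0]))[0]
        summaries[d] = (n, top[0], top[1])

    # --- merge, percentile, combined score, rank
    universe = sorted(set(tx_scores) | set(pm_totals) | set(ok_scores))
    n = len(universe)
    tx_raw = [tx_scores.get(d, 0.0) for d in universe]
    pm_raw = [float(pm_totals.get(d, 0)) for d in universe]
    ok_raw = [ok_scores.get(d, 0.0) for d in universe]

    def pct(values):
        return [sum(1 for u in values if u <= v) / n for v in values]

    tx_pct, pm_pct, ok_pct = pct(tx_raw), pct(pm_raw), pct(ok_raw)
    out_rows = []
    for i, d in enumerate(universe):
        support = sum(1 for v in (tx_raw[i], pm_raw[i], ok_raw[i]) if v > 0)
        clinical = 1 if d in summaries else 0
        score = (
            0.50 * tx_pct[i]
            + 0.40 * pm_pct[i]
            + 0.10 * ok_pct[i]
            + 0.20 * max(0, support - 1)
            + 0.30 * (1.0 if ok_raw[i] > 0 else 0.0)
            + 0.05 * clinical
        )
        summ = summaries.get(d)
        out_rows.append(
            {
                "drug": d,
                "txgnn_score": tx_raw[i],
                "mention_count": int(pm_raw[i]),
                "oncokb_score": ok_raw[i],
                "tx_pct": tx_pct[i],
                "pm_pct": pm_pct[i],
                "ok_pct": ok_pct[i],
                "support_count": support,
                "clinical_flag": clinical,
                "combined_score": score,
                "n_clinical_trials": summ[0] if summ else 0,
                "top_nct_id": summ[1] if summ else "",
                "top_phase": summ[2] if summ else "",
            }
        )
    out_rows.sort(key=lambda r: (-r["combined_score"], -r["support_count"], r["drug"]))
    for rank, row in enumerate(out_rows, start=1):
        row["rank"] = rank
    columns = [
        "drug", "txgnn_score", "mention_count", "oncokb_score", "tx_pct",
        "pm_pct", "ok_pct", "support_count", "clinical_flag", "combined_score",
        "rank", "n_clinical_trials", "top_nct_id", "top_phase",
    ]
    return pd.DataFrame(out_rows, columns=columns)
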
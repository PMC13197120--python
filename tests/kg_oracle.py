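"""Independent brute-force oracle for knowledge-graph candidate retrieval.

Used by the KG unit tests and the acceptance suite. Works directly on raw
(source, source_type, relation, target, target_type) rows with nested loops;
shares no code with idap.evidence_kg or idap.fixtures.
"""

import random


def random_toy_graph(rng: random.Random, max_nodes=100, max_edges=400):
    """Random typed graph rows plus a query disease, gene set and FDA list."""
    n_disease = rng.randint(1, 4)
    n_drug = rng.randint(2, max(2, max_nodes // 3))
    n_gene = rng.randint(2, max(2, max_nodes // 3))
    diseases = [f"DIS{i}" for i in range(n_disease)]
    drugs = [f"DR{i}" for i in range(n_drug)]
    genes = [f"GN{i}" for i in range(n_gene)]
    relations = ["indication", "drug-protein", "off-label use", "contraindication"]
    rows = []
    for _ in range(rng.randint(3, max_edges)):
        rel = rng.choice(relations)
        if rel == "drug-protein":
            rows.append((rng.choice(drugs), "drug", rel, rng.choice(genes), "gene/protein"))
        else:
            d, dis = rng.choice(drugs), rng.choice(diseases)
            if rng.random() < 0.5:
                rows.append((d, "drug", rel, dis, "disease"))
            else:
                rows.append((dis, "disease", rel, d, "drug"))
    query = rng.choice(diseases)
    mutated = sorted(rng.sample(genes, rng.randint(0, min(5, n_gene))))
    fda = {d for d in drugs if rng.random() < 0.5}
    return rows, query, mutated, fda


def brute_force_candidates(rows, disease_id, mutated_genes, fda,
                           base=None, bonus=10.0):
    """Triple-scan categorization and scoring; returns {drug: (category,
    frozenset(targets), score)}. Node ids double as names here."""
    if base is None:
        base = {
            "REPURPOSING_PRIORITY": 100.0,
            "TARGET_UNAPPROVED": 60.0,
            "CURRENT_INDICATION": 40.0,
            "DISEASE_RELATED": 20.0,
        }
    triples = set()
    node_type = {}
    for s, st, rel, t, tt in rows:
        triples.add((s, rel, t))
        node_type[s] = st
        node_type[t] = tt
    drugs = sorted(n for n, ty in node_type.items() if ty == "drug")
    mutated = set(mutated_genes)
    out = {}
    for drug in drugs:
        has_indication = False
        targets = set()
        related = False
        for s, rel, t in triples:
            pair = {s, t}
            if drug not in pair:
                continue
            other = t if s == drug else s
            if rel == "indication" and other == disease_id:
                has_indication = True
            if rel == "drug-protein" and node_type[other] == "gene/protein" and other in mutated:
                targets.add(other)
            if rel != "indication" and other == disease_id and node_type[other] == "disease":
                related = True
        if has_indication:
            cat = "CURRENT_INDICATION"
        elif targets:
            cat = "REPURPOSING_PRIORITY" if drug in fda else "TARGET_UNAPPROVED"
        elif related:
            cat = "DISEASE_RELATED"
        else:
            continue
        score = base[cat] + bonus * max(0, len(targets) - 1)
        out[drug] = (cat, frozenset(targets), score)
    return out
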
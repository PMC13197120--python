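# IDAP — Integrated Drug Annotation Pipeline

IDAP turns a tumor's somatic mutation profile into a ranked, evidence-layered
list of therapeutic hypotheses for expert review. Most variants detected by
routine tumor sequencing have no entry in curated precision-oncology
knowledge bases, so IDAP integrates four complementary evidence streams per
drug:

1. **Curated** — OncoKB-annotator output: variant-drug associations with
   clinical evidence levels, reduced to a per-drug `oncokb_score`.
2. **Literature** — abstracts retrieved per altered gene with the query
   `"<cancer type> AND <gene> AND (therapy OR treatment OR inhibitor)"`,
   scanned for drug names from a normalized anticancer lexicon and summarized
   as gene-drug `mention_count`s.
3. **Graph** — a typed biomedical knowledge graph (diseases, drugs,
   genes/proteins). Drugs are retrieved via `indication` edges to the query
   cancer, `drug-protein` edges to mutated genes, and FDA-approval
   cross-referencing, then scored by a mutation-aware heuristic
   (`txgnn_score`); drugs approved for *other* diseases that target mutated
   genes form the repurposing-priority category.
4. **Clinical trials** — per-drug unique-trial counts and a highest-phase
   representative trial, setting a `clinical_flag`.

Raw layer scores are incommensurable, so each is converted to a
within-sample percentile (inclusive empirical CDF over the sample's
candidate drugs) and combined as

```
combined_score = 0.50·tx_pct + 0.40·pm_pct + 0.10·ok_pct
               + 0.20·max(0, support_count − 1)
               + 0.30·I(oncokb_score > 0)
               + 0.05·clinical_flag
```

where `support_count` is the number of score layers with positive signal.
The maximum attainable score under default weights is 1.75. Outputs are
prioritized hypotheses, not clinical recommendations.

## Worked example

Everything runs offline from an evidence bundle — a directory holding the
standard input files (MAF, knowledge-graph edge list, FDA list, drug-name
source tables, abstract corpus, trial records, annotated MAF). A fully
synthetic bundle with a known expected ranking ships with the package:

```bash
idap fixtures --seed 7 --out demo_bundle
idap run --maf demo_bundle/sample.maf --cancer-type "lung cancer" \
         --bundle demo_bundle --out demo_out
```

prints

```
22 candidate drug(s); top-1 TORILIMUS (combined_score 1.3364, support 3, clinical_flag 1)
report: demo_out/report.html
```

meaning the sample yielded 22 candidate drugs across the evidence layers and
the top hypothesis is supported by all three score layers (graph, literature
and curated evidence) plus matched trial metadata — 1.3364 out of the 1.75
maximum. `demo_out/` contains the self-contained HTML report (sample
summary, top-20 bar chart, cancer-gene-drug network, ranked table) plus
`ranked_drugs.tsv`, `variants.tsv` and `network_edges.tsv`. The first
ranked rows:

```
drug        txgnn_score  mention_count  oncokb_score  ...  combined_score  rank
TORILIMUS   50.0         4              1.5           ...  1.3364          1
ALPEPARIB   100.0        5              0.0           ...  1.1091          2
DOCERABINE  100.0        5              0.0           ...  1.1091          3
```

Two companion commands:

```bash
idap sensitivity --maf demo_bundle/sample.maf --cancer-type "lung cancer" \
                 --bundle demo_bundle             # re-rank under alternative weights
idap benchmark --ranked demo_out/ranked_drugs.tsv \
               --truth demo_bundle/truth_set.tsv  # first-match rank, top-10 recovery
```

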
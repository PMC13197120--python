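# Methods

## Problem and scope

Given one tumor sample's somatic mutations (a MAF file) and a cancer-type
label, IDAP produces a ranked list of candidate drugs, each annotated with
the evidence layers supporting it. The package integrates evidence; it does
not call variants (input is a finished MAF), does not re-curate knowledge
bases, and does not perform graph-neural-network inference — the knowledge
graph is used as a structured resource, traversed with explicit rules.

## Evidence layers

**Gene extraction.** Gene symbols are whitespace-trimmed, uppercased and
deduplicated; all downstream joins are symbol-string joins, so
normalization happens once, here and in the drug lexicon. Silent/intronic
variants are not filtered by default (a classification blocklist is
available) because the evidence layers operate at gene level and gene
membership, not variant consequence, drives retrieval.

**Drug lexicon.** All layers share one vocabulary: canonical names plus an
alias map, normalized by trim/collapse/uppercase. Text matching is
whole-word with boundaries at non-alphanumeric characters; multi-word names
match as contiguous normalized phrases. Whole-word (rather than substring)
matching is a deliberate choice: substring matching on short drug names
produces pathological false positives. Alias collisions resolve to the
first-seen canonical with a warning, keeping the canonical set
order-insensitive.

**Curated layer.** OncoKB-annotator output is ingested from file (two drug
column dialects: per-level columns, or one `drugs` column inheriting the
row's highest level). The per-drug score is the maximum of a configurable
level→value map over all (variant, level) pairs:
LEVEL_1→4, LEVEL_2→3, LEVEL_3A→2, LEVEL_3B→1.5, LEVEL_4→1, resistance
levels→0. Only the *order* of these values matters — the ranking consumes
the score through its within-sample percentile and a positivity
indicator — so any order-preserving map yields identical ranks. Resistance
levels are excluded from positive evidence because they indicate
non-response.

**Literature layer.** One query per altered gene
(`"<cancer type> AND <gene> AND (therapy OR treatment OR inhibitor)"`).
Mentions are counted per *distinct abstract*, not per occurrence (repeated
mentions within one abstract are not independent evidence; a per-occurrence
mode exists). Abstract identifiers are kept in a provenance table; the
merged output exposes only counts. The layer is evidence retrieval, not
relation extraction: no NER, negation handling, or causality.

**Graph layer.** Candidates are categorized
CURRENT_INDICATION (indication edge to the query disease) >
REPURPOSING_PRIORITY (FDA-approved, targets ≥1 mutated gene via
drug-protein edge, no indication edge) >
TARGET_UNAPPROVED (targets mutated genes, not approved) >
DISEASE_RELATED (any other disease-drug relation to the query disease),
with that precedence on overlap. Scores are
`base(category) + 10 × max(0, n_targeted_genes − 1)` with bases
100/60/40/20. TARGET_UNAPPROVED is placed above CURRENT_INDICATION in base
score because it is mutation-linked; both orderings are defensible and the
table is configurable — after percentile normalization only the ordering
matters. Edges are queried undirected; the cancer-type string is grounded
to a disease node via a user map with exact name match as fallback.

**Trial layer.** Per drug: unique NCT count and a representative trial of
maximal phase priority (PHASE4 > … > PHASE1; early-phase, not-applicable
and unknown phases floor at 0; combined phases take their highest
component). Phase ties break by smallest NCT id, purely for determinism.
No condition-relevance filtering is applied; conditions are stored
verbatim.

## Ranking

The candidate universe is the union of drugs in the three score layers.
Trial-only drugs are excluded: the clinical layer attaches metadata to
candidates rather than nominating them. Percentiles are inclusive empirical
CDFs, pct(v) = #{u ≤ v}/N, so the lowest tied block receives its share of
mass and the maximum is exactly 1. `support_count` counts the three score
layers only (the clinical layer has its own term), capping the multi-source
bonus at 0.40 and the total at 1.75 under default weights. Sort order:
combined score desc, support desc, name asc; ranks are a permutation of
1..N and the output is byte-deterministic.

The weight-sensitivity harness re-ranks under alternative
(w_tx, w_pm, w_ok) triples — default list: the six permutations of
(0.5, 0.4, 0.1) plus uniform — reporting per-configuration top-1 and top-k
overlap against the default, and whether the top-1 drug is stable across
all configurations. The truth-set benchmark reports eligibility (non-empty
truth set), recovery anywhere in the list, first-match rank, and top-10
membership.

## Synthetic data

The fixture generator emulates one sample of a named cancer type: ~8 driver
genes, ~24 invented single-token drug names (so whole-word matching reduces
to token equality in fixtures; multi-word matching is covered by dedicated
unit fixtures), a knowledge graph with indication / drug-protein /
off-label / distractor edges, an abstract corpus mentioning drugs by name
or alias, trial tables with mixed and combined phases, an annotated MAF
with ~25% curated rows, and a truth set drawn from the expected ranking.
Evidence sparsity mirrors the method's target regime: most drugs supported
by one layer, a minority curated or multi-source. It does not emulate
realistic mutation spectra, literature volume, or cohort-scale variability
— green tests show the machinery is correct, not that the ranking is
clinically calibrated.

Every bundle ships with the ranked table computed by a naive, loop-based
reference implementation embedded in the generator and sharing no code with
the pipeline: two independent implementations must agree exactly (same
order, scores identical) on every generated bundle. Unit tests add a third
independent brute-force oracle for graph retrieval on random toy graphs.

## Numerical choices and degenerate inputs

- Percentile and combined-score arithmetic is plain IEEE double; the oracle
  transcribes the same expression order, so agreement is exact, not
  approximate.
- Empty gene set, empty corpus, empty universe: valid inputs producing
  empty (not error) results; the report renders an explicit "no
  candidates" section and the CLI exits 0.
- All table outputs are written with `\n` line endings and no timestamps
  (deterministic mode, default) so repeated runs are byte-identical.
- Problem sizes used by the test suite and acceptance script (toy graphs
  ≤100 nodes, cohorts of 10 synthetic samples) were chosen as the smallest
  sizes that exercise every category, tie-break and bonus path.

## Online adapters

Live PubMed E-utilities, ClinicalTrials.gov v2 and ChEMBL harvesting are
opt-in adapters that write the same file formats the offline pipeline
reads. Rate limiting defaults to 0.3 s between queries; trial queries use
`"<drug> AND <cancer type>"` with up to 200 records per drug. Retrieval
windows and `retmax` have no authoritative values and are configurable.
Adapters are excluded from the offline test surface.

## Known limitations

Co-mention counts are not causal evidence; the heuristic graph scores
encode category ordering, not effect size; the combined score is not
trained on clinical outcomes; name-string joins cannot resolve chemical
identity (salt forms, combination products). Ranked output is a triage aid
for expert review.
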
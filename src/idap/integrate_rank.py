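"""Evidence merging, percentile normalization, combined scoring and ranking.

The three score-bearing layers (graph ``txgnn_score``, literature
``mention_count``, curated ``oncokb_score``) live on incompatible raw scales.
Within each sample they are converted to inclusive empirical-CDF percentiles
over the candidate universe, pct(v) = #{values <= v} / N, so tied values
share a percentile and the maximum is exactly 1. The combined score is then

    combined_score = w_tx * tx_pct + w_pm * pm_pct + w_ok * ok_pct
                   + 0.20 * max(0, support_count - 1)
                   + 0.30 * I(oncokb_score > 0)
                   + 0.05 * clinical_flag

with default weights (w_tx, w_pm, w_ok) = (0.50, 0.40, 0.10). support_count
is the number of score layers with positive raw signal (max 3, so the
multi-source bonus caps at 0.40); clinical_flag marks drugs with at least one
matched trial record. The maximum attainable default-weight score is 1.75.
The score is a transparent prioritization heuristic, not a model trained on
clinical outcomes.

The candidate universe is the union of drugs in the three score layers;
trial-only drugs do not enter the ranking (the clinical layer attaches to
candidates, it does not create them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .evidence_kg import KGCandidate
from .evidence_literature import MentionCounts
from .evidence_oncokb import OncoKBDrugEvidence
from .evidence_trials import TrialSummary

RANKED_COLUMNS = [
    "drug",
    "txgnn_score",
    "mention_count",
    "oncokb_score",
    "tx_pct",
    "pm_pct",
    "ok_pct",
    "support_count",
    "clinical_flag",
    "combined_score",
    "rank",
    "n_clinical_trials",
    "top_nct_id",
    "top_phase",
]


@dataclass(frozen=True)
class WeightConfig:
    """Percentile weights plus the fixed evidence bonuses."""

    w_tx: float = 0.50
    w_pm: float = 0.40
    w_ok: float = 0.10
    bonus_multisource: float = 0.20
    bonus_oncokb: float = 0.30
    bonus_clinical: float = 0.05

    def __post_init__(self) -> None:
        for name in ("w_tx", "w_pm", "w_ok", "bonus_multisource", "bonus_oncokb", "bonus_clinical"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def label(self) -> str:
        return f"({self.w_tx:g},{self.w_pm:g},{self.w_ok:g})"


#: Default sensitivity harness configurations: the six permutations of the
#: default weight triple plus the uniform configuration.
DEFAULT_SENSITIVITY_CONFIGS: tuple[WeightConfig, ...] = tuple(
    WeightConfig(w_tx=a, w_pm=b, w_ok=c)
    for a, b, c in [
        (0.50, 0.40, 0.10),
        (0.50, 0.10, 0.40),
        (0.40, 0.50, 0.10),
        (0.40, 0.10, 0.50),
        (0.10, 0.50, 0.40),
        (0.10, 0.40, 0.50),
        (1 / 3, 1 / 3, 1 / 3),
    ]
)


def within_sample_percentile(values: Sequence[float]) -> list[float]:
    """Inclusive empirical-CDF percentile of each value among all values.

    pct(v) = #{u : u <= v} / N; ties share a percentile; max maps to 1.0;
    every output lies in (0, 1]. Empty input returns empty output.
    """
    n = len(values)
    if n == 0:
        return []
    arr = np.asarray(values, dtype=float)
    order = np.sort(arr)
    return (np.searchsorted(order, arr, side="right") / n).tolist()


def combined_score(
    tx_pct: float,
    pm_pct: float,
    ok_pct: float,
    support_count: int,
    oncokb_positive: bool,
    clinical_flag: int,
    weights: Optional[WeightConfig] = None,
) -> float:
    """Evaluate the combined-score formula exactly as stated above."""
    w = weights or WeightConfig()
    return (
        w.w_tx * tx_pct
        + w.w_pm * pm_pct
        + w.w_ok * ok_pct
        + w.bonus_multisource * max(0, support_count - 1)
        + w.bonus_oncokb * (1.0 if oncokb_positive else 0.0)
        + w.bonus_clinical * clinical_flag
    )


def merge_and_rank(
    oncokb: OncoKBDrugEvidence,
    mentions: MentionCounts,
    kg_candidates: Iterable[KGCandidate],
    trials: Mapping[str, TrialSummary],
    weights: Optional[WeightConfig] = None,
) -> pd.DataFrame:
    """Merge the evidence layers into the ranked candidate table.

    Drugs absent from a layer enter with raw value 0. Ties in combined score
    break by higher support_count, then alphabetical drug name; ranks are
    1..N. Deterministic: identical inputs yield byte-identical tables.
    """
    weights = weights or WeightConfig()
    kg_scores = {c.drug: c.txgnn_score for c in kg_candidates}
    mention_totals = mentions.totals
    universe = sorted(set(kg_scores) | set(mention_totals) | set(oncokb.scores))
    if not universe:
        return pd.DataFrame(columns=RANKED_COLUMNS)

    tx_raw = [kg_scores.get(d, 0.0) for d in universe]
    pm_raw = [float(mention_totals.get(d, 0)) for d in universe]
    ok_raw = [oncokb.scores.get(d, 0.0) for d in universe]
    tx_pct = within_sample_percentile(tx_raw)
    pm_pct = within_sample_percentile(pm_raw)
    ok_pct = within_sample_percentile(ok_raw)

    rows = []
    for i, drug in enumerate(universe):
        support = sum(1 for v in (tx_raw[i], pm_raw[i], ok_raw[i]) if v > 0)
        clinical = 1 if drug in trials else 0
        score = combined_score(
            tx_pct[i], pm_pct[i], ok_pct[i], support, ok_raw[i] > 0, clinical, weights
        )
        summary = trials.get(drug)
        rows.append(
            {
                "drug": drug,
                "txgnn_score": tx_raw[i],
                "mention_count": int(pm_raw[i]),
                "oncokb_score": ok_raw[i],
                "tx_pct": tx_pct[i],
                "pm_pct": pm_pct[i],
                "ok_pct": ok_pct[i],
                "support_count": support,
                "clinical_flag": clinical,
                "combined_score": score,
                "n_clinical_trials": summary.n_clinical_trials if summary else 0,
                "top_nct_id": summary.top_nct_id if summary else "",
                "top_phase": summary.top_phase if summary else "",
            }
        )
    rows.sort(key=lambda r: (-r["combined_score"], -r["support_count"], r["drug"]))
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank
    return pd.DataFrame(rows, columns=RANKED_COLUMNS)


@dataclass(frozen=True)
class SensitivityRow:
    """Ranking behaviour of one weight configuration vs the default."""

    config: WeightConfig
    top1: Optional[str]
    topk_overlap: float
    same_top1_as_default: bool


@dataclass(frozen=True)
class SensitivityResult:
    default_top1: Optional[str]
    rows: tuple[SensitivityRow, ...]
    top1_stable: bool  # identical top-1 across all configurations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "config": r.config.label(),
                    "top1": r.top1 or "",
                    "topk_overlap": r.topk_overlap,
                    "same_top1_as_default": r.same_top1_as_default,
                }
                for r in self.rows
            ]
        )


def weight_sensitivity(
    oncokb: OncoKBDrugEvidence,
    mentions: MentionCounts,
    kg_candidates: Sequence[KGCandidate],
    trials: Mapping[str, TrialSummary],
    configs: Sequence[WeightConfig],
    default: Optional[WeightConfig] = None,
    top_k: int = 10,
) -> SensitivityResult:
    """Re-rank under alternative weight configurations and compare to default.

    Reports, per configuration, the top-1 drug and the fraction of top-k
    overlap with the default ranking, plus whether the top-1 drug is stable
    across every configuration.
    """
    if len(configs) < 2:
        raise ValueError("need at least two weight configurations")
    default = default or WeightConfig()

    def rank_with(w: WeightConfig) -> pd.DataFrame:
        return merge_and_rank(oncokb, mentions, kg_candidates, trials, w)

    base = rank_with(default)
    base_top1 = base["drug"].iloc[0] if len(base) else None
    base_topk = set(base["drug"].head(top_k))
    rows = []
    for cfg in configs:
        ranked = rank_with(cfg)
        top1 = ranked["drug"].iloc[0] if len(ranked) else None
        topk = set(ranked["drug"].head(top_k))
        overlap = len(base_topk & topk) / len(base_topk) if base_topk else 1.0
        rows.append(
            SensitivityRow(
                config=cfg,
                top1=top1,
                topk_overlap=overlap,
                same_top1_as_default=top1 == base_top1,
            )
        )
    stable = all(r.same_top1_as_default for r in rows)
    return SensitivityResult(default_top1=base_top1, rows=tuple(rows), top1_stable=stable)


@dataclass(frozen=True)
class BenchmarkResult:
    """Truth-set recovery of a ranked list (first-match rank, top-10 hit)."""

    eligible: bool
    recovered: bool
    first_match_rank: Optional[int]
    top10_hit: bool


def benchmark_truthset(ranked: pd.DataFrame, truth: set[str]) -> BenchmarkResult:
    """Scan a ranked table for truth-set drugs.

    A sample is eligible when the truth set is non-empty; recovery means any
    truth drug appears anywhere in the ranking.
    """
    eligible = bool(truth)
    if not eligible:
        return BenchmarkResult(False, False, None, False)
    first: Optional[int] = None
    if len(ranked):
        hits = ranked[ranked["drug"].isin(truth)]
        if len(hits):
            first = int(hits["rank"].min())
    return BenchmarkResult(
        eligible=True,
        recovered=first is not None,
        first_match_rank=first,
        top10_hit=first is not None and first <= 10,
    )
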
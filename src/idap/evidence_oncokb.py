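"""Curated variant-drug evidence: ingesting OncoKB-annotator output.

The annotator attaches, per variant, an oncogenicity call, a clinical evidence
level (LEVEL_1 strongest … LEVEL_4, plus resistance levels R1/R2) and the
drugs supported at that level. This module parses that output and converts it
into a per-drug ``oncokb_score``. The numeric value of the score is a
configurable order-preserving map over levels — only its within-sample
percentile and its positivity indicator enter the final ranking, so any
order-preserving choice yields identical ranks.

Calling the live annotation API is not part of this module; it consumes the
annotator's output files only.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .lexicon import DrugLexicon, normalize_name

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("ONCOGENIC", "HIGHEST_LEVEL", "VARIANT_IN_ONCOKB")

#: Order-preserving map from evidence level to score. Resistance levels map
#: to 0: they indicate non-response and are excluded from positive evidence.
DEFAULT_LEVEL_MAP: dict[str, float] = {
    "LEVEL_1": 4.0,
    "LEVEL_2": 3.0,
    "LEVEL_3A": 2.0,
    "LEVEL_3B": 1.5,
    "LEVEL_4": 1.0,
    "LEVEL_R1": 0.0,
    "LEVEL_R2": 0.0,
}

_TRUE_STRINGS = {"TRUE", "T", "1", "YES", "Y"}
_DRUG_SPLIT = re.compile(r"[,;]")


@dataclass(frozen=True)
class OncoKBAnnotation:
    """Curated evidence attached to one annotated variant row."""

    gene: str
    protein_change: Optional[str]
    oncogenic: str
    highest_level: Optional[str]
    variant_in_oncokb: bool
    drug_levels: tuple[tuple[str, Optional[str]], ...]  # (drug, level) pairs

    def __post_init__(self) -> None:
        if not self.variant_in_oncokb and self.highest_level is not None:
            raise ValueError("highest_level must be absent when variant not in OncoKB")

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.drug_levels)


@dataclass
class OncoKBDrugEvidence:
    """Per-drug curated-evidence layer: score and best supporting level."""

    scores: dict[str, float] = field(default_factory=dict)
    best_level: dict[str, Optional[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scores)


def _parse_bool(value: str) -> bool:
    return str(value).strip().upper() in _TRUE_STRINGS


def _split_drugs(cell: str) -> list[str]:
    return [d.strip() for d in _DRUG_SPLIT.split(str(cell)) if d.strip()]


def parse_annotated_maf(
    path: str | Path, lexicon: Optional[DrugLexicon] = None
) -> list[OncoKBAnnotation]:
    """Parse OncoKB-annotator TSV output into annotation records.

    Two drug-column dialects are accepted: per-level columns (``LEVEL_1`` …
    ``LEVEL_R2``, each holding the drugs supported at that level) or a single
    ``drugs`` column whose entries inherit the row's ``HIGHEST_LEVEL``.
    Drug strings are split on comma/semicolon and canonicalized through the
    lexicon when one is supplied.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"annotated MAF {path} lacks required OncoKB column(s): {', '.join(missing)}"
        )
    level_columns = [c for c in frame.columns if re.fullmatch(r"LEVEL_\w+", c)]
    drugs_column = next((c for c in frame.columns if c.lower() == "drugs"), None)

    def canon(name: str) -> str:
        return lexicon.canonicalize(name) if lexicon is not None else normalize_name(name)

    annotations: list[OncoKBAnnotation] = []
    for _, row in frame.iterrows():
        in_oncokb = _parse_bool(row["VARIANT_IN_ONCOKB"])
        level = str(row["HIGHEST_LEVEL"]).strip() or None
        if not in_oncokb:
            level = None
        pairs: list[tuple[str, Optional[str]]] = []
        if in_oncokb:
            for col in level_columns:
                for drug in _split_drugs(row[col]):
                    pairs.append((canon(drug), col))
            if drugs_column and not level_columns:
                for drug in _split_drugs(row[drugs_column]):
                    pairs.append((canon(drug), level))
        annotations.append(
            OncoKBAnnotation(
                gene=str(row.get("Hugo_Symbol", "")).strip().upper(),
                protein_change=str(row.get("HGVSp_Short", "")).strip() or None,
                oncogenic=str(row["ONCOGENIC"]).strip(),
                highest_level=level,
                variant_in_oncokb=in_oncokb,
                drug_levels=tuple(pairs),
            )
        )
    return annotations


def score_oncokb_drugs(
    annotations: Iterable[OncoKBAnnotation],
    level_map: Optional[Mapping[str, float]] = None,
) -> OncoKBDrugEvidence:
    """Per-drug score = max mapped level value over all (variant, level) pairs.

    Unknown level strings map to 0 with a warning. Adding an annotation can
    never decrease a drug's score (max is monotone under evidence addition).
    """
    if level_map is None:
        level_map = DEFAULT_LEVEL_MAP
    if any(v < 0 for v in level_map.values()):
        raise ValueError("level_map values must be >= 0")
    evidence = OncoKBDrugEvidence()
    for ann in annotations:
        for drug, level in sorted(ann.drug_levels):
            if level is None:
                value = 0.0
            elif level in level_map:
                value = float(level_map[level])
            else:
                logger.warning("unknown OncoKB level %r treated as 0", level)
                value = 0.0
            if drug not in evidence.scores or value > evidence.scores[drug]:
                evidence.scores[drug] = value
                evidence.best_level[drug] = level
    return evidence
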
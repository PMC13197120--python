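"""Clinical-trial evidence: per-drug trial counts and top-phase selection.

Trial records carry the registry fields drug, nct_id, title, condition,
phase, status — one row per (drug, trial) as fetched. Summaries count unique
NCT identifiers per drug and pick one representative trial with the highest
phase (Phase 4 > Phase 3 > Phase 2 > Phase 1; early-phase/NA/unknown rank
lowest), breaking phase ties by the lexicographically smallest NCT id so the
choice is deterministic. Presence of any summary row for a drug sets the
clinical_flag used by the ranking layer.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

_NCT = re.compile(r"NCT\d+")

#: Registry token priorities; unknown or not-applicable phases floor at 0.
DEFAULT_PHASE_PRIORITIES: dict[str, int] = {
    "PHASE1": 1,
    "PHASE2": 2,
    "PHASE3": 3,
    "PHASE4": 4,
    "EARLY_PHASE1": 0,
    "NA": 0,
}


@dataclass(frozen=True)
class TrialRecord:
    drug: str
    nct_id: str
    title: str
    condition: str
    phase: str
    status: str

    def __post_init__(self) -> None:
        if not self.nct_id:
            raise ValueError("nct_id must be non-empty")


@dataclass(frozen=True)
class TrialSummary:
    drug: str
    n_clinical_trials: int
    top_nct_id: str
    top_phase: str
    top_title: str


def normalize_phase(phase: str) -> str:
    """Map free-text phase strings to registry tokens (``Phase 3`` → PHASE3)."""
    token = re.sub(r"[\s_]+", "_", phase.strip().upper())
    token = re.sub(r"^PHASE_(\d)$", r"PHASE\1", token)
    return token


def phase_priority(
    phase: str, priorities: Optional[Mapping[str, int]] = None
) -> int:
    """Priority of a phase string; combined phases (``PHASE2|PHASE3``) take
    the highest component; unrecognized phases → 0."""
    if priorities is None:
        priorities = DEFAULT_PHASE_PRIORITIES
    parts = re.split(r"[|/,]", phase or "")
    best = 0
    for part in parts:
        best = max(best, priorities.get(normalize_phase(part), 0))
    return best


def summarize_trials(
    records: Iterable[TrialRecord],
    priorities: Optional[Mapping[str, int]] = None,
) -> dict[str, TrialSummary]:
    """Group records by drug into :class:`TrialSummary` rows.

    Duplicated rows do not inflate counts; drugs with zero records are simply
    absent (their clinical_flag is 0 downstream).
    """
    by_drug: dict[str, list[TrialRecord]] = {}
    for rec in records:
        by_drug.setdefault(rec.drug, []).append(rec)
    summaries: dict[str, TrialSummary] = {}
    for drug in sorted(by_drug):
        rows = by_drug[drug]
        n = len({r.nct_id for r in rows})
        top = min(rows, key=lambda r: (-phase_priority(r.phase, priorities), r.nct_id))
        summaries[drug] = TrialSummary(
            drug=drug,
            n_clinical_trials=n,
            top_nct_id=top.nct_id,
            top_phase=top.phase,
            top_title=top.title,
        )
    return summaries


def summaries_to_frame(summaries: Mapping[str, TrialSummary]) -> pd.DataFrame:
    rows = [
        {
            "drug": s.drug,
            "n_clinical_trials": s.n_clinical_trials,
            "top_nct_id": s.top_nct_id,
            "top_phase": s.top_phase,
            "top_title": s.top_title,
        }
        for s in summaries.values()
    ]
    return pd.DataFrame(
        rows, columns=["drug", "n_clinical_trials", "top_nct_id", "top_phase", "top_title"]
    )


def read_trial_records(path: str | Path) -> list[TrialRecord]:
    """Read trial records from JSON-lines or TSV (six registry fields)."""
    path = Path(path)
    fields = ("drug", "nct_id", "title", "condition", "phase", "status")
    records = []
    if path.suffix in {".jsonl", ".json"}:
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            records.append(TrialRecord(**{f: str(obj.get(f, "")) for f in fields}))
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [f for f in fields if f not in frame.columns]
        if missing:
            raise ValueError(f"trial table {path} lacks column(s): {', '.join(missing)}")
        for row in frame.itertuples(index=False):
            records.append(TrialRecord(**{f: str(getattr(row, f)) for f in fields}))
    return records
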
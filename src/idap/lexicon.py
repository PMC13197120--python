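"""Normalized anticancer drug vocabulary and whole-word mention matching.

The lexicon is the single point of drug-name canonicalization: every layer
(curated annotations, literature mentions, knowledge-graph candidates, trial
records) joins on the canonical names produced here. Matching against free
text is whole-word — substring matching on short drug names produces
pathological false positives — with word boundaries at non-alphanumeric
characters and multi-word names matched as contiguous normalized phrases.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalize_name(raw: str) -> str:
    """Trim, collapse internal whitespace, uppercase. Idempotent."""
    return _WS.sub(" ", raw.strip()).upper()


@dataclass
class DrugLexicon:
    """Canonical drug names plus an alias map (aliases normalized identically).

    Invariants: every alias maps to exactly one canonical; every canonical
    maps to itself; no empty strings.
    """

    canonical_names: set[str] = field(default_factory=set)
    alias_map: dict[str, str] = field(default_factory=dict)
    _pattern: Optional[re.Pattern] = field(default=None, repr=False, compare=False)

    def canonicalize(self, raw: str) -> str:
        """Map a raw name to its canonical form; unknown names are returned
        normalized but not added to the lexicon."""
        norm = normalize_name(raw)
        return self.alias_map.get(norm, norm)

    def __contains__(self, raw: str) -> bool:
        return normalize_name(raw) in self.alias_map

    def __len__(self) -> int:
        return len(self.canonical_names)

    def _compiled(self) -> Optional[re.Pattern]:
        if self._pattern is None and self.alias_map:
            # Longest-first alternation so multi-word phrases win over their
            # single-word prefixes; boundaries at non-alphanumerics.
            alts = sorted(self.alias_map, key=lambda s: (-len(s), s))
            body = "|".join(re.escape(a) for a in alts)
            self._pattern = re.compile(
                r"(?<![A-Z0-9])(?:" + body + r")(?![A-Z0-9])"
            )
        return self._pattern


def build_lexicon(source_tables: Iterable[tuple[str, Iterable[str]]]) -> DrugLexicon:
    """Union drug-name sources into one deduplicated vocabulary.

    Each record is ``(name, aliases)``. Duplicates collapse after
    normalization; an alias claimed by two canonicals resolves to the
    first-seen canonical with a logged warning, which makes the resulting
    canonical set order-insensitive even though alias ownership is not.
    """
    lex = DrugLexicon()
    for name, aliases in source_tables:
        canon = normalize_name(name)
        if not canon:
            logger.warning("skipping source record with empty drug name")
            continue
        existing = lex.alias_map.get(canon)
        if existing is None:
            lex.canonical_names.add(canon)
            lex.alias_map[canon] = canon
        elif existing != canon:
            logger.warning(
                "name %r already registered as alias of %r; keeping first-seen",
                canon,
                existing,
            )
            continue
        for alias in aliases:
            anorm = normalize_name(alias)
            if not anorm:
                continue
            owner = lex.alias_map.get(anorm)
            if owner is None:
                lex.alias_map[anorm] = canon
            elif owner != canon:
                logger.warning(
                    "alias %r claimed by %r and %r; keeping first-seen %r",
                    anorm,
                    owner,
                    canon,
                    owner,
                )
    lex._pattern = None
    return lex


def match_mentions(text: str, lexicon: DrugLexicon) -> set[str]:
    """Canonical drugs whose name or alias occurs whole-word in *text*."""
    pattern = lexicon._compiled()
    if pattern is None or not text:
        return set()
    norm = normalize_name(text)
    return {lexicon.alias_map[m] for m in pattern.findall(norm)}


def count_occurrences(text: str, lexicon: DrugLexicon) -> dict[str, int]:
    """Per-canonical-drug occurrence counts (for per-occurrence mention mode)."""
    pattern = lexicon._compiled()
    if pattern is None or not text:
        return {}
    counts: dict[str, int] = {}
    for m in pattern.findall(normalize_name(text)):
        canon = lexicon.alias_map[m]
        counts[canon] = counts.get(canon, 0) + 1
    return counts


def read_source_table(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read a drug-source TSV with columns ``name`` and optional ``aliases``
    (semicolon-separated)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "name" not in frame.columns:
        raise ValueError(f"drug source table {path} lacks required column 'name'")
    records = []
    for _, row in frame.iterrows():
        aliases = [a for a in str(row.get("aliases", "")).split(";") if a.strip()]
        records.append((str(row["name"]), aliases))
    return records


def read_fda_list(path: str | Path) -> set[str]:
    """FDA-approved drug list: plain text, one name per line, normalized."""
    names = set()
    for line in Path(path).read_text().splitlines():
        norm = normalize_name(line)
        if norm:
            names.add(norm)
    return names
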
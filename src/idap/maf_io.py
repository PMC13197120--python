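"""Reading MAF (Mutation Annotation Format) files and extracting altered genes.

A MAF file carries one somatic mutation per row, keyed by the ``Hugo_Symbol``
gene name. The pipeline needs only the set of altered gene symbols per sample;
coordinate-level fields are carried through opaquely for the variant table in
the report, but no coordinate computation is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Optional MAF columns recognised by :func:`read_maf`; anything else is kept
#: in :attr:`MafVariant.extras`.
OPTIONAL_COLUMNS = {
    "Chromosome": "chromosome",
    "Start_Position": "start_position",
    "Reference_Allele": "reference_allele",
    "Tumor_Seq_Allele2": "alternate_allele",
    "Variant_Classification": "variant_classification",
    "HGVSp_Short": "protein_change",
    "Tumor_Sample_Barcode": "sample_id",
}


@dataclass(frozen=True)
class MafVariant:
    """One somatic mutation row.

    Only ``hugo_symbol`` is required; all other fields default to neutral
    values when the corresponding MAF column is absent.
    """

    hugo_symbol: str
    chromosome: str = ""
    start_position: int = 1
    reference_allele: str = ""
    alternate_allele: str = ""
    variant_classification: str = ""
    protein_change: Optional[str] = None
    sample_id: str = ""
    extras: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.hugo_symbol.strip():
            raise ValueError("hugo_symbol must be non-empty after trimming")
        if self.start_position < 1:
            raise ValueError("start_position must be >= 1")


@dataclass(frozen=True)
class GeneSet:
    """Unique, uppercased, lexicographically sorted altered gene symbols.

    ``n_variants`` counts the variant rows the symbols were extracted from;
    one gene may carry many variants, so ``n_variants >= len(genes)`` whenever
    ``genes`` is non-empty.
    """

    genes: tuple[str, ...]
    n_variants: int

    def __post_init__(self) -> None:
        if list(self.genes) != sorted(set(self.genes)):
            raise ValueError("genes must be unique and lexicographically sorted")
        if self.genes and self.n_variants < 1:
            raise ValueError("n_variants must be >= 1 when genes is non-empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def read_maf(path: str | Path) -> list[MafVariant]:
    """Read a tab-separated MAF file into :class:`MafVariant` records.

    Lines starting with ``#`` (version pragmas etc.) are skipped. Rows with an
    empty ``Hugo_Symbol`` are dropped with a warning — real MAFs contain
    intergenic rows. A missing ``Hugo_Symbol`` column is a hard error.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read MAF file {path}: {exc}") from exc
    if "Hugo_Symbol" not in frame.columns:
        raise ValueError(f"MAF file {path} lacks required column Hugo_Symbol")

    variants: list[MafVariant] = []
    n_dropped = 0
    known = {"Hugo_Symbol", *OPTIONAL_COLUMNS}
    extra_cols = [c for c in frame.columns if c not in known]
    for row in frame.itertuples(index=False):
        record = dict(zip(frame.columns, row))
        symbol = str(record["Hugo_Symbol"]).strip()
        if not symbol:
            n_dropped += 1
            continue
        kwargs: dict = {"hugo_symbol": symbol}
        for col, attr in OPTIONAL_COLUMNS.items():
            if col in record and str(record[col]) != "":
                value: object = str(record[col])
                if attr == "start_position":
                    value = int(float(value))
                kwargs[attr] = value
        if extra_cols:
            kwargs["extras"] = {c: str(record[c]) for c in extra_cols}
        variants.append(MafVariant(**kwargs))
    if n_dropped:
        logger.warning("dropped %d MAF row(s) with empty Hugo_Symbol", n_dropped)
    return variants


def extract_genes(
    variants: Iterable[MafVariant],
    exclude_classifications: Optional[Sequence[str]] = None,
) -> GeneSet:
    """Collapse variants to the per-sample altered gene set.

    Symbols are whitespace-trimmed and uppercased before deduplication
    (MAF dialects vary in case) because downstream knowledge-graph and
    literature joins are symbol-string joins. ``exclude_classifications``
    optionally drops variant classes (e.g. ``Silent``) before extraction;
    by default nothing is filtered.
    """
    blocklist = {c.strip().upper() for c in exclude_classifications or ()}
    kept = [
        v
        for v in variants
        if v.variant_classification.strip().upper() not in blocklist
    ]
    symbols = sorted({v.hugo_symbol.strip().upper() for v in kept})
    return GeneSet(genes=tuple(symbols), n_variants=len(kept))


def variants_to_frame(variants: Sequence[MafVariant]) -> pd.DataFrame:
    """Tabulate variants for the report's variant table."""
    rows = [
        {
            "Hugo_Symbol": v.hugo_symbol,
            "Chromosome": v.chromosome,
            "Start_Position": v.start_position,
            "Reference_Allele": v.reference_allele,
            "Tumor_Seq_Allele2": v.alternate_allele,
            "Variant_Classification": v.variant_classification,
            "HGVSp_Short": v.protein_change or "",
            "Tumor_Sample_Barcode": v.sample_id,
        }
        for v in variants
    ]
    columns = [
        "Hugo_Symbol",
        "Chromosome",
        "Start_Position",
        "Reference_Allele",
        "Tumor_Seq_Allele2",
        "Variant_Classification",
        "HGVSp_Short",
        "Tumor_Sample_Barcode",
    ]
    return pd.DataFrame(rows, columns=columns)
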
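"""Online adapters: optional live harvesting into the offline file formats.

Each adapter writes exactly the file format the corresponding evidence
module reads, so a refreshed bundle is interchangeable with a synthetic or
cached one. All adapters are opt-in (``idap run --online``), rate-limited,
and excluded from the offline test surface; they use only the standard
library HTTP client.

Defaults that the upstream services do not pin (retrieval window, page
sizes) are configurable and documented as unknowns:

* PubMed E-utilities: query template
  ``"<cancer type> AND <gene> AND (therapy OR treatment OR inhibitor)"``,
  ``retmax`` abstracts per gene (default 100 — no published value).
* ClinicalTrials.gov v2 ``/studies``: query ``"<drug> AND <cancer type>"``,
  up to 200 records per drug, fields extracted from ``protocolSection``.
* ChEMBL: drug names from indication/mechanism/ATC/approval endpoints,
  written as a standard (name, aliases) source table.
"""

from __future__ import annotations

import json
import time
import urllib.parse
import urllib.request
from pathlib import Path
from typing import Iterable, Sequence

from .evidence_literature import build_query

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
CTGOV = "https://clinicaltrials.gov/api/v2/studies"

#: Fixed inter-query delay in seconds, to avoid overloading public services.
DEFAULT_DELAY_S = 0.3


def _get_json(url: str, timeout: float = 30.0) -> dict:
    with urllib.request.urlopen(url, timeout=timeout) as response:  # pragma: no cover
        return json.loads(response.read().decode("utf-8"))


def fetch_abstracts(
    cancer_type: str,
    genes: Iterable[str],
    out_path: str | Path,
    retmax: int = 100,
    delay_s: float = DEFAULT_DELAY_S,
) -> int:  # pragma: no cover - network
    """Fetch PubMed abstracts per gene into a JSON-lines corpus file."""
    n = 0
    with open(out_path, "w") as handle:
        for gene in genes:
            query = build_query(cancer_type, gene)
            search = _get_json(
                f"{EUTILS}/esearch.fcgi?db=pubmed&retmode=json&retmax={retmax}"
                f"&term={urllib.parse.quote(query)}"
            )
            ids = search.get("esearchresult", {}).get("idlist", [])
            for pmid in ids:
                time.sleep(delay_s)
                summary = _get_json(
                    f"{EUTILS}/efetch.fcgi?db=pubmed&retmode=json&id={pmid}"
                )
                handle.write(
                    json.dumps(
                        {
                            "gene_query": gene,
                            "abstract_id": f"PMID{pmid}",
                            "text": json.dumps(summary),
                        }
                    )
                    + "\n"
                )
                n += 1
            time.sleep(delay_s)
    return n


def fetch_trials(
    cancer_type: str,
    drugs: Sequence[str],
    out_path: str | Path,
    page_size: int = 200,
    delay_s: float = DEFAULT_DELAY_S,
) -> int:  # pragma: no cover - network
    """Fetch trial records per drug into the six-field TSV format."""
    n = 0
    with open(out_path, "w") as handle:
        handle.write("drug\tnct_id\ttitle\tcondition\tphase\tstatus\n")
        for drug in drugs:
            query = urllib.parse.quote(f"{drug} AND {cancer_type}")
            payload = _get_json(f"{CTGOV}?query.term={query}&pageSize={page_size}")
            for study in payload.get("studies", []):
                protocol = study.get("protocolSection", {})
                ident = protocol.get("identificationModule", {})
                design = protocol.get("designModule", {})
                status_mod = protocol.get("statusModule", {})
                cond = protocol.get("conditionsModule", {})
                handle.write(
                    "\t".join(
                        [
                            drug,
                            ident.get("nctId", ""),
                            ident.get("briefTitle", "").replace("\t", " "),
                            "; ".join(cond.get("conditions", [])),
                            "|".join(design.get("phases", []) or ["NA"]),
                            status_mod.get("overallStatus", ""),
                        ]
                    )
                    + "\n"
                )
                n += 1
            time.sleep(delay_s)
    return n


def fetch_chembl_lexicon(out_path: str | Path) -> int:  # pragma: no cover - network
    """Stub: harvest anticancer drug names into a (name, aliases) source
    table. Left as a stub — the lexicon builds only from local tables."""
    raise NotImplementedError(
        "live ChEMBL harvesting is not implemented; supply a local source table"
    )
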
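"""End-to-end extraction over JSON-lines corpora.

Documents come in as JSON-lines ({"id": ..., "text": ...}); predictions
and gold annotations use the same record shape: id plus three lists of
normalized entity strings (primary_sites, primary_sizes,
metastatic_sites).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .lexicon import Lexicon
from .metastasis import extract_metastatic_sites
from .primary_site import extract_primary_sites
from .text_prep import Document
from .tumor_size import extract_primary_sizes, normalize_size


@dataclass(frozen=True)
class RunConfig:
    """Pipeline flags; the defaults reproduce the reference rule set."""

    multi_primary: bool = False
    negation_policy: str = "substring"  # or "drop-negated"
    unit_policy: str = "propagate"      # or "as_parsed"
    variant_expansion: bool = True
    refine_skip_metastasis: bool = True


def extract_document(doc: Document, lexicon: Lexicon, config: RunConfig | None = None) -> dict:
    """Run all three extractors on one document.

    Returns a prediction record: ``{"id", "primary_sites",
    "primary_sizes", "metastatic_sites"}`` with normalized entity strings.
    """
    config = config or RunConfig()
    primaries = extract_primary_sites(
        doc, lexicon, multi_primary=config.multi_primary,
        refine_skip_metastasis=config.refine_skip_metastasis)
    sizes = extract_primary_sizes(
        doc, primaries, lexicon, unit_policy=config.unit_policy,
        variant_expansion=config.variant_expansion)
    metas = extract_metastatic_sites(doc, lexicon, negation_policy=config.negation_policy)
    return {
        "id": doc.id,
        "primary_sites": [m.normalized for m in primaries],
        "primary_sizes": [normalize_size(m, policy=config.unit_policy) for m in sizes],
        "metastatic_sites": [m.normalized for m in metas],
    }


def extract_corpus(docs: Iterable[Document], lexicon: Lexicon,
                   config: RunConfig | None = None) -> list[dict]:
    """Extract every document; deterministic given input and config."""
    return [extract_document(doc, lexicon, config) for doc in docs]


def read_documents_jsonl(path: str | Path) -> list[Document]:
    """Read documents from JSON-lines with fields ``id`` and ``text``."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON line: {exc}") from exc
            if "id" not in rec or "text" not in rec:
                raise ValueError(f"{path}:{lineno}: record needs 'id' and 'text' fields")
            docs.append(Document(id=str(rec["id"]), text=rec["text"]))
    return docs


def read_records_jsonl(path: str | Path) -> dict[str, dict]:
    """Read prediction/gold records keyed by document id."""
    records: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON line: {exc}") from exc
            if "id" not in rec:
                raise ValueError(f"{path}:{lineno}: record needs an 'id' field")
            records[str(rec["id"])] = rec
    return records


def write_jsonl(records: Iterable[dict], path: str | Path) -> None:
    """Write records as UTF-8 JSON-lines (keys in insertion order)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_gold_csv(path: str | Path, id_col: str = "id",
                  primary_col: str = "primary_sites", size_col: str = "primary_sizes",
                  meta_col: str = "metastatic_sites", list_sep: str = "|",
                  delimiter: str = ",") -> dict[str, dict]:
    """Import shim for tabular gold files.

    Each entity column holds a ``list_sep``-separated list of entity
    strings; empty cells mean no entities.
    """
    records: dict[str, dict] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delimiter):
            def split(col: str) -> list[str]:
                cell = (row.get(col) or "").strip()
                return [v.strip() for v in cell.split(list_sep) if v.strip()] if cell else []
            records[str(row[id_col])] = {
                "id": str(row[id_col]),
                "primary_sites": split(primary_col),
                "primary_sizes": split(size_col),
                "metastatic_sites": split(meta_col),
            }
    return records
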
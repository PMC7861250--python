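"""Primary tumor size extraction.

Size expressions in Chinese radiology reports are strongly patterned:
1–3 decimal dimensions with optional CM/MM units, joined by ×, X, x or *,
optionally preceded by a qualifier (约 "approximately", 不足 "less than",
大小约 "size approximately").  Extraction is a three-step procedure:

1. detect sentences matched by the size grammar,
2. keep only sentences related to the primary tumor (they contain a
   laterality variant of a primary site, or are the primary-site sentence
   itself; sentences with a density indicator rank first),
3. extract all leftmost-longest non-overlapping matches and parse them.

A match must carry at least one explicit unit, which keeps dates and other
bare-number runs out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .lexicon import Lexicon, expand_site_variants
from .primary_site import EntityMention
from .text_prep import Document, Sentence, fold_for_match, split_sentences

_NUM = r"\d+(?:\.\d+)?"
_UNIT = r"(?:CM|MM)"
_SEP = r"\s*[×X*]\s*"
_DIM = rf"{_NUM}(?:{_UNIT})?"
_BODY = rf"{_DIM}(?:{_SEP}{_DIM}){{0,2}}"
_QUAL = r"(?:(?:大小)?(?P<qual>不足|约)\s*)?"

#: full pattern over width/case-folded text
SIZE_PATTERN = re.compile(rf"{_QUAL}(?P<body>{_BODY})")
_DIM_PATTERN = re.compile(rf"(?P<num>{_NUM})(?P<unit>{_UNIT})?")
_SEP_PATTERN = re.compile(r"[×X*]")


class Dimension(NamedTuple):
    """One measured extent: numeric value, unit, and the raw digit string."""

    value: float
    unit: str  # "cm" | "mm" | "unspecified"
    text: str


@dataclass(frozen=True)
class SizeMention:
    """A parsed size expression.

    ``raw`` is the verbatim sentence substring at ``span`` (the dimension
    body, excluding any qualifier); ``qualifier`` carries 约 or 不足 when
    present.
    """

    raw: str
    dimensions: tuple[Dimension, ...]
    separator: str | None
    qualifier: str | None
    sentence_index: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.dimensions) <= 3:
            raise ValueError("a size mention has 1 to 3 dimensions")
        if any(d.value <= 0 for d in self.dimensions):
            raise ValueError("dimension values must be positive")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def extract_size_mentions(sentence: Sentence | str, sentence_index: int | None = None) -> list[SizeMention]:
    """All non-overlapping, leftmost-longest size matches in a sentence.

    Matching runs on the width/case-folded text (offsets are shared with
    the original).  Candidate matches without any explicit CM/MM unit are
    rejected, so bare numbers and dates never produce mentions.
    """
    if isinstance(sentence, Sentence):
        text, index = sentence.text, sentence.index
    else:
        text, index = sentence, (sentence_index if sentence_index is not None else 0)
    folded = fold_for_match(text)
    mentions: list[SizeMention] = []
    for match in SIZE_PATTERN.finditer(folded):
        body = match.group("body")
        if "CM" not in body and "MM" not in body:
            continue
        start, end = match.start("body"), match.end("body")
        dims = tuple(
            Dimension(value=float(m.group("num")),
                      unit={None: "unspecified", "CM": "cm", "MM": "mm"}[m.group("unit")],
                      text=m.group("num"))
            for m in _DIM_PATTERN.finditer(body)
        )
        sep_match = _SEP_PATTERN.search(body)
        mentions.append(SizeMention(
            raw=text[start:end],
            dimensions=dims,
            separator=text[start + sep_match.start()] if sep_match else None,
            qualifier=match.group("qual"),
            sentence_index=index,
            start=start,
            end=end,
        ))
    return mentions


def detect_size_sentences(doc: Document) -> list[Sentence]:
    """Sentences of the document matched by the size grammar, in order."""
    return [s for s in split_sentences(doc) if extract_size_mentions(s)]


def filter_primary_related(sentences: list[Sentence], primary_sites: Sequence[EntityMention | str],
                           lexicon: Lexicon, variant_expansion: bool = True) -> list[Sentence]:
    """Keep size sentences related to the primary tumor.

    A sentence survives when it contains any laterality variant of a
    primary site, or is the sentence the primary-site mention came from.
    Size extraction is defined relative to a primary site: with no primary
    sites the result is empty.  Among survivors, sentences containing a
    density indicator (高密度影, 低密度影, 不规则团块, ...) rank first.
    Primary sites may be given as plain strings when no mention objects
    are available.
    """
    if not primary_sites:
        return []
    site_forms: set[str] = set()
    primary_sentence_indexes = {m.sentence_index for m in primary_sites
                                if isinstance(m, EntityMention)}
    for mention in primary_sites:
        surfaces = ((mention, mention) if isinstance(mention, str)
                    else (mention.normalized, mention.surface))
        for surface in surfaces:
            if variant_expansion:
                site_forms.update(fold_for_match(v) for v in expand_site_variants(surface))
            else:
                site_forms.add(fold_for_match(surface))
    survivors = []
    for sentence in sentences:
        folded = fold_for_match(sentence.text)
        if sentence.index in primary_sentence_indexes or any(f in folded for f in site_forms):
            survivors.append(sentence)
    with_density = [s for s in survivors
                    if lexicon.contains_keyword(s.text, lexicon.density_indicators)]
    without = [s for s in survivors if s not in with_density]
    return with_density + without


def normalize_size(mention: SizeMention, policy: str = "propagate") -> str:
    """Canonical surface of a size mention, e.g. ``1.3CMx1.7CM``.

    Dimensions joined by a folded lowercase ``x`` with uppercase units.
    Under the default ``propagate`` policy, unit-less dimensions inherit
    the last explicit unit of the mention (5x4x3CM → 5CMx4CMx3CM); with
    ``as_parsed`` they stay bare.
    """
    if policy not in ("propagate", "as_parsed"):
        raise ValueError(f"unknown unit policy: {policy!r}")
    fill = ""
    if policy == "propagate":
        for dim in reversed(mention.dimensions):
            if dim.unit != "unspecified":
                fill = dim.unit.upper()
                break
    parts = []
    for dim in mention.dimensions:
        unit = dim.unit.upper() if dim.unit != "unspecified" else fill
        parts.append(f"{dim.text}{unit}")
    return "x".join(parts)


def extract_primary_sizes(doc: Document, primary_sites: Sequence[EntityMention | str], lexicon: Lexicon,
                          unit_policy: str = "propagate", variant_expansion: bool = True) -> list[SizeMention]:
    """Full size pipeline: detect → primary-relatedness filter → extract.

    Mentions are returned in document order, deduplicated on their
    normalized form.
    """
    sentences = detect_size_sentences(doc)
    survivors = filter_primary_related(sentences, primary_sites, lexicon,
                                       variant_expansion=variant_expansion)
    mentions: list[SizeMention] = []
    for sentence in survivors:
        mentions.extend(extract_size_mentions(sentence))
    mentions.sort(key=lambda m: (m.sentence_index, m.start))
    out: list[SizeMention] = []
    seen: set[str] = set()
    for mention in mentions:
        key = normalize_size(mention, policy=unit_policy)
        if key not in seen:
            seen.add(key)
            out.append(mention)
    return out
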
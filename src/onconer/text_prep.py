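"""Sentence decomposition, dictionary tokenization and descriptor stripping.

Chinese radiology reports are processed at sentence granularity: keyword
filters, anatomy matching and size regexes all operate on single
sentences.  Tokenization exists purely to serve dictionary matching — every
lexicon term occurring in a sentence must surface as one unbroken token
(longest-match priority).  No general-purpose NLP (POS tagging, parsing)
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterator

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon import Lexicon

#: Characters that end a sentence.  The full-width comma ，/, does NOT
#: split: clinical size statements routinely continue across commas
#: ("...密度灶,大小约1.3CM × 1.7CM,边缘分叶...") and must stay in one
#: sentence context.
SENTENCE_DELIMITERS = frozenset("。；;！？\n")

_FULLWIDTH_OFFSET = 0xFEE0


def fold_width(text: str) -> str:
    """Fold full-width ASCII variants (ＦＷ forms, ideographic space) to ASCII.

    The mapping is one-to-one per code point, so character offsets in the
    folded string are valid offsets into the original.
    """
    out = []
    for ch in text:
        o = ord(ch)
        if 0xFF01 <= o <= 0xFF5E:
            out.append(chr(o - _FULLWIDTH_OFFSET))
        elif o == 0x3000:
            out.append(" ")
        else:
            out.append(ch)
    return "".join(out)


def fold_for_match(text: str) -> str:
    """Width-fold and uppercase ASCII letters; length-preserving.

    Used for all pattern matching (MT/CA indicators, CM/MM units) so that
    case and width variants compare equal.  Original surfaces are kept for
    spans and output.
    """
    folded = fold_width(text)
    return "".join(chr(ord(c) - 32) if "a" <= c <= "z" else c for c in folded)


@dataclass(frozen=True)
class Document:
    """A single report: an identifier and its verbatim UTF-8 text."""

    id: str
    text: str


@dataclass(frozen=True)
class Sentence:
    """One sentence of a document.

    ``text`` is the exact substring ``document.text[start:end]`` including
    any trailing delimiter run, so concatenating the texts of all
    sentences reconstructs the document exactly.  ``content`` strips the
    trailing delimiters.
    """

    index: int
    text: str
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def content(self) -> str:
        return self.text.rstrip("".join(SENTENCE_DELIMITERS))

    @property
    def delimiter(self) -> str:
        return self.text[len(self.content):]


def split_sentences(doc: Document) -> list[Sentence]:
    """Split a document into sentences on 。；;！？ and newline.

    Delimiters attach to the preceding sentence; a run of consecutive
    delimiters stays together.  Fragments consisting only of delimiters
    (a document starting with a delimiter) are folded into the adjacent
    sentence so that no text is lost.  Empty text yields an empty list.
    """
    text = doc.text
    if not text:
        return []
    # cut after every maximal delimiter run
    cuts: list[int] = []
    i, n = 0, len(text)
    while i < n:
        if text[i] in SENTENCE_DELIMITERS:
            j = i
            while j < n and text[j] in SENTENCE_DELIMITERS:
                j += 1
            cuts.append(j)
            i = j
        else:
            i += 1
    if not cuts or cuts[-1] != n:
        cuts.append(n)
    sentences: list[Sentence] = []
    prev = 0
    for cut in cuts:
        seg = text[prev:cut]
        if not seg:
            continue
        if all(c in SENTENCE_DELIMITERS for c in seg):
            # orphan delimiter run: no preceding content (document head);
            # leave it to be absorbed by the next segment
            continue
        sentences.append(Sentence(index=len(sentences), text=text[_seg_start(sentences, prev):cut],
                                  start=_seg_start(sentences, prev), end=cut))
        prev = cut
    if sentences and sentences[-1].end != n:
        # trailing orphan delimiters: extend the last sentence
        last = sentences[-1]
        sentences[-1] = Sentence(index=last.index, text=text[last.start:n], start=last.start, end=n)
    if not sentences:
        # degenerate document of delimiters only: keep it as one sentence
        # so no text is ever lost
        sentences = [Sentence(index=0, text=text, start=0, end=n)]
    return sentences


def _seg_start(sentences: list[Sentence], default: int) -> int:
    """Start of the next segment: right after the previous sentence, so any
    skipped leading delimiter run is absorbed."""
    return sentences[-1].end if sentences else 0


def segment(sentence: Sentence | str, lexicon: "Lexicon") -> list[str]:
    """Tokenize a sentence with the lexicon as segmentation dictionary.

    Greedy longest-match, left to right, over every lexicon term (anatomy
    terms including their laterality variants, keywords, descriptors,
    conjunctions).  Characters not covered by any term are grouped into
    maximal unmatched runs.  Concatenating the tokens reproduces the input
    exactly.
    """
    return [tok for tok, _start in segment_with_spans(sentence, lexicon)]


def segment_with_spans(sentence: Sentence | str, lexicon: "Lexicon") -> list[tuple[str, int]]:
    """Like :func:`segment` but returns ``(token, start_offset)`` pairs."""
    text = sentence.text if isinstance(sentence, Sentence) else sentence
    folded = fold_for_match(text)
    table, max_len = lexicon.term_table()
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(folded)
    pending = 0  # start of current unmatched run
    while i < n:
        match_len = 0
        for length in range(min(max_len, n - i), 0, -1):
            if folded[i:i + length] in table:
                match_len = length
                break
        if match_len:
            if pending < i:
                tokens.append((text[pending:i], pending))
            tokens.append((text[i:i + match_len], i))
            i += match_len
            pending = i
        else:
            i += 1
    if pending < n:
        tokens.append((text[pending:], pending))
    return tokens


def strip_descriptive_words(phrase: str, lexicon: "Lexicon") -> str:
    """Remove descriptor terms (多发肿大, 小, ...) from an anatomic phrase.

    Tokenization-aware: descriptors embedded in a longer lexicon anatomy
    term survive (小 inside 小肠), because the anatomy term wins
    longest-match and is never broken.  Removal is repeated to a fixed
    point so the operation is idempotent.
    """
    descriptors = lexicon.descriptor_terms
    if not descriptors:
        return phrase
    current = phrase
    for _ in range(10):  # fixed point is reached almost immediately
        parts = []
        changed = False
        for tok, _start in segment_with_spans(current, lexicon):
            if tok in descriptors or fold_for_match(tok) in lexicon._descriptor_folded:
                changed = True
                continue
            parts.append(tok)
        nxt = "".join(parts)
        if not changed or nxt == current:
            return nxt
        current = nxt
    return current
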
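"""Metastatic tumor site recognition.

Metastatic sites are anatomic positions co-occurring, in the same
sentence, with metastasis-indicating keywords (转移, 考虑转移, 多发转移).
Recognition is rule-based:

1. key-sentence acquisition: keep sentences containing a metastasis
   keyword;
2. phrase detection: inside a key sentence, anatomy-bearing noun phrases
   are maximal contiguous runs of anatomy terms, descriptor terms,
   locative characters (内/部/旁) and conjunction tokens, truncated at the
   run's last anatomy token;
3. descriptive-word stripping (纵隔内多发肿大淋巴结 → 纵隔内淋巴结);
4. coordination-ellipsis completion: a shared head noun elided from all
   but the last conjunct is restored (肺门及前纵隔淋巴结 → 肺门淋巴结,
   前纵隔淋巴结).

Plain substring matching on 转移 treats double negatives (转移不除外) as
positive mentions, which is the desired reading; ``negation_policy=
"drop-negated"`` instead drops sentences with single-negated metastasis
(未见/无…转移) unless a double-negative cue (不除外/不能除外/待排) is present.
"""

from __future__ import annotations

import re

from .lexicon import Lexicon, canonical_site
from .primary_site import META_SITE, EntityMention
from .text_prep import Document, Sentence, fold_width, segment_with_spans, split_sentences, strip_descriptive_words

LOCATIVE_CHARS = frozenset("内部旁")

_SINGLE_NEGATION = re.compile(r"(?:未见|未|无|没有)[^,，。;；]*转移")
_DOUBLE_NEGATION = re.compile(r"不除外|不能除外|待排|可能")


def filter_metastasis_sentences(doc: Document, lexicon: Lexicon,
                                negation_policy: str = "substring") -> list[Sentence]:
    """Sentences containing at least one metastasis keyword, in order."""
    if negation_policy not in ("substring", "drop-negated"):
        raise ValueError(f"unknown negation policy: {negation_policy!r}")
    out = []
    for sentence in split_sentences(doc):
        if not lexicon.contains_keyword(sentence.text, lexicon.metastasis_keywords):
            continue
        if negation_policy == "drop-negated":
            folded = fold_width(sentence.text)
            if _SINGLE_NEGATION.search(folded) and not _DOUBLE_NEGATION.search(folded):
                continue
        out.append(sentence)
    return out


def complete_conjoined_entities(phrase: str, lexicon: Lexicon) -> list[str]:
    """Restore a shared suffix elided from coordinated anatomic conjuncts.

    The phrase is split on conjunction tokens (、, 及, 与).  The shared
    suffix is the longest lexicon anatomy term that is a proper suffix of
    the last conjunct (fallback: its trailing segmentation token); it is
    appended to every conjunct not already ending with it.  A phrase with
    no conjunction — or whose last conjunct IS the identified suffix, i.e.
    a plain list with nothing elided — comes back as-is.
    """
    if not phrase:
        raise ValueError("phrase must be non-empty")
    tokens = sorted(lexicon.conjunction_tokens, key=len, reverse=True)
    pattern = "|".join(re.escape(t) for t in tokens)
    conjuncts = [c.strip() for c in re.split(pattern, phrase) if c.strip()]
    if len(conjuncts) <= 1:
        return [phrase]
    last = conjuncts[-1]
    suffix = _shared_suffix(last, lexicon)
    if suffix is None or suffix == last:
        return conjuncts
    return [c if c.endswith(suffix) else c + suffix for c in conjuncts]


def _shared_suffix(conjunct: str, lexicon: Lexicon) -> str | None:
    """Longest anatomy term that is a proper suffix of the conjunct;
    fallback: its trailing segmentation token."""
    best: str | None = None
    for length in range(len(conjunct) - 1, 0, -1):
        tail = conjunct[-length:]
        if lexicon.is_anatomy(tail):
            best = tail
            break
    if best is None:
        toks = segment_with_spans(conjunct, lexicon)
        if toks:
            best = toks[-1][0]
    return best


def _anatomy_phrases(sentence: Sentence, lexicon: Lexicon) -> list[tuple[str, int, int]]:
    """Maximal anatomy-bearing noun-phrase runs in a sentence.

    A run is a contiguous span of anatomy terms, descriptor terms,
    conjunction tokens and locative characters; it is truncated at its last
    anatomy token and must contain at least one.  Returns (phrase, start,
    end) triples with offsets into the sentence text.
    """
    tokens = segment_with_spans(sentence, lexicon)
    conjunctions = set(lexicon.conjunction_tokens)

    def allowed(tok: str) -> bool:
        if tok in conjunctions or lexicon.is_anatomy(tok) or lexicon.is_descriptor(tok):
            return True
        return all(c in LOCATIVE_CHARS for c in tok)

    phrases: list[tuple[str, int, int]] = []
    run: list[tuple[str, int]] = []
    for tok, start in tokens + [("", -1)]:  # sentinel flushes the last run
        if tok and allowed(tok):
            run.append((tok, start))
            continue
        if run:
            # truncate at the last anatomy token
            last_anat = None
            for k, (rtok, _rs) in enumerate(run):
                if lexicon.is_anatomy(rtok):
                    last_anat = k
            if last_anat is not None:
                kept = run[:last_anat + 1]
                p_start = kept[0][1]
                p_end = kept[-1][1] + len(kept[-1][0])
                phrases.append((sentence.text[p_start:p_end], p_start, p_end))
        run = []
    return phrases


def extract_metastatic_sites(doc: Document, lexicon: Lexicon,
                             negation_policy: str = "substring") -> list[EntityMention]:
    """Recognize metastatic sites of a document.

    Per key sentence: anatomy-bearing phrases are located, descriptors
    stripped, conjunction ellipsis completed, and one META_SITE mention
    emitted per completed entity.  Duplicates are folded across the
    document on the laterality-normalized form.
    """
    mentions: list[EntityMention] = []
    seen: set[str] = set()
    for sentence in filter_metastasis_sentences(doc, lexicon, negation_policy=negation_policy):
        for phrase, start, end in _anatomy_phrases(sentence, lexicon):
            core = strip_descriptive_words(phrase, lexicon)
            if not core:
                continue
            for entity in complete_conjoined_entities(core, lexicon):
                normalized = fold_width(entity)
                key = canonical_site(normalized)
                if key in seen:
                    continue
                seen.add(key)
                mentions.append(EntityMention(
                    surface=phrase, normalized=normalized, etype=META_SITE,
                    sentence_index=sentence.index, start=start, end=end))
    return mentions
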
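"""Primary tumor site identification.

A primary tumor site is the first anatomic site mentioned in a report that
is associated with a malignancy description (癌, 恶性, 瘤, MT, CA, ...) and
not with metastasis.  The pipeline: keep sentences containing a malignancy
indicator, drop those containing a metastasis keyword, match anatomy terms
against the segmented sentence, take the first mention in document order,
then refine an approximate site (肺) to a more specific one (左肺上叶) found
elsewhere in the document via the part-of relation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .lexicon import Lexicon, canonical_site, is_part_of
from .text_prep import Document, Sentence, fold_width, segment_with_spans, split_sentences, strip_descriptive_words

PRIMARY_SITE = "PRIMARY_SITE"
TUMOR_SIZE = "TUMOR_SIZE"
META_SITE = "META_SITE"


@dataclass(frozen=True)
class EntityMention:
    """An extracted surface string with type, span and normalized form.

    ``surface`` is the exact sentence substring at ``span``.  ``normalized``
    is the surface after width-folding and descriptor stripping; for
    conjunction-completed metastatic sites it is the completed entity,
    which may extend beyond the surface.
    """

    surface: str
    normalized: str
    etype: str
    sentence_index: int
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def filter_malignancy_sentences(doc: Document, lexicon: Lexicon) -> list[Sentence]:
    """Sentences containing at least one malignancy indicator.

    Matching is substring-based after width folding; Latin abbreviations
    (MT, CA) match case-insensitively.  Order is preserved.
    """
    return [s for s in split_sentences(doc)
            if lexicon.contains_keyword(s.text, lexicon.malignancy_indicators)]


def _contains_metastasis(sentence: Sentence, lexicon: Lexicon) -> bool:
    return lexicon.contains_keyword(sentence.text, lexicon.metastasis_keywords)


def match_anatomy_mentions(sentence: Sentence, lexicon: Lexicon) -> list[EntityMention]:
    """One PRIMARY_SITE mention per token that is an anatomy term.

    A token whose descriptor-stripped form is an anatomy term also counts
    (e.g. a phrase token wrapping the bare site).  Mentions come back in
    sentence order with correct spans.
    """
    mentions: list[EntityMention] = []
    for token, start in segment_with_spans(sentence, lexicon):
        if lexicon.is_anatomy(token):
            normalized = fold_width(token)
        else:
            stripped = strip_descriptive_words(token, lexicon)
            if stripped and stripped != token and lexicon.is_anatomy(stripped):
                normalized = fold_width(stripped)
            else:
                continue
        mentions.append(EntityMention(
            surface=token, normalized=normalized, etype=PRIMARY_SITE,
            sentence_index=sentence.index, start=start, end=start + len(token)))
    return mentions


def refine_primary_site(approximate: EntityMention, doc: Document, lexicon: Lexicon,
                        skip_metastasis: bool = True) -> EntityMention:
    """Replace an approximate site with the first more-specific mention.

    Scans every sentence of the document in order for an anatomy mention
    that is a proper part of the approximate site (左肺上叶 refines 肺);
    returns the approximate mention unchanged when none exists.  Sentences
    containing metastasis keywords are skipped by default, consistent with
    the requirement that the primary site not be metastasis-related.
    """
    for sentence in split_sentences(doc):
        if skip_metastasis and _contains_metastasis(sentence, lexicon):
            continue
        for mention in match_anatomy_mentions(sentence, lexicon):
            if is_part_of(mention.normalized, approximate.normalized):
                return replace(mention, etype=PRIMARY_SITE)
    return approximate


def extract_primary_sites(doc: Document, lexicon: Lexicon, multi_primary: bool = False,
                          refine_skip_metastasis: bool = True) -> list[EntityMention]:
    """Identify the primary tumor site(s) of a document.

    Default behaviour returns at most one site: the first anatomy mention,
    in document order, from a sentence that contains a malignancy
    indicator and no metastasis keyword, refined to the most specific
    part-of mention found elsewhere.  With ``multi_primary=True`` every
    surviving malignancy sentence contributes its first anatomy mention —
    an extension beyond the default single-primary behaviour.
    """
    candidates: list[EntityMention] = []
    for sentence in filter_malignancy_sentences(doc, lexicon):
        if _contains_metastasis(sentence, lexicon):
            continue
        mentions = match_anatomy_mentions(sentence, lexicon)
        if not mentions:
            continue
        candidates.append(mentions[0])
        if not multi_primary:
            break
    results: list[EntityMention] = []
    seen: set[str] = set()
    for cand in candidates:
        refined = refine_primary_site(cand, doc, lexicon, skip_metastasis=refine_skip_metastasis)
        key = canonical_site(refined.normalized)
        if key not in seen:
            seen.add(key)
            results.append(refined)
    return results
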
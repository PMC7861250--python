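import random

import pytest

from onconer import (
    Document,
    detect_size_sentences,
    extract_primary_sites,
    extract_primary_sizes,
    extract_size_mentions,
    filter_primary_related,
    normalize_size,
    split_sentences,
)
from onconer.text_prep import fold_for_match


# ---------------------------------------------------------------------------
# brute-force oracle: hand-rolled character scanner, independent of the regex
# ---------------------------------------------------------------------------

def _size_body_len_at(s: str, i: int) -> int | None:
    """Length of the longest size-expression body starting at s[i] that
    contains at least one explicit unit; None if there is none."""
    n = len(s)

    def read_number(j):
        k = j
        while k < n and s[k].isdigit():
            k += 1
        if k == j:
            return None
        if k < n and s[k] == ".":
            m = k + 1
            while m < n and s[m].isdigit():
                m += 1
            if m > k + 1:
                return m
        return k

    best = None
    j, dims, units = i, 0, 0
    while dims < 3:
        k = read_number(j)
        if k is None:
            break
        if s[k:k + 2].upper() in ("CM", "MM"):
            k += 2
            units += 1
        dims += 1
        if units:
            best = k - i
        m = k
        while m < n and s[m] in " \t":
            m += 1
        if m < n and s[m] in "×Xx*":
            m += 1
            while m < n and s[m] in " \t":
                m += 1
            j = m
        else:
            break
    return best


def brute_force_size_spans(text: str) -> list[tuple[int, int]]:
    """Leftmost-longest non-overlapping size bodies by exhaustive scan."""
    folded = fold_for_match(text)
    spans, i = [], 0
    while i < len(folded):
        length = _size_body_len_at(folded, i)
        if length:
            spans.append((i, i + length))
            i += length
        else:
            i += 1
    return spans


_NOISE = "左肺上叶示一不规则软组织密度灶边缘分叶可见强化大小约不足纵隔淋巴结,，。"


def _random_size_text(rng: random.Random) -> str:
    from onconer import gen_size_string
    parts = ["".join(rng.choices(_NOISE, k=rng.randint(0, 8)))]
    for _ in range(rng.randint(1, 2)):
        surface, _norm = gen_size_string(rng)
        parts.append(surface)
        parts.append("".join(rng.choices(_NOISE, k=rng.randint(1, 8))))
    return "".join(parts)


class TestSizeGrammar:
    @pytest.mark.parametrize("exemplar,normalized", [
        ("5x4x3CM", "5CMx4CMx3CM"),
        ("2.0X2CM", "2.0CMx2CM"),
        ("5CM*5MM", "5CMx5MM"),
        ("不足 5CM", "5CM"),
    ])
    def test_reference_formats_match(self, exemplar, normalized):
        mentions = extract_size_mentions(exemplar)
        assert len(mentions) == 1
        assert normalize_size(mentions[0]) == normalized

    def test_qualifier_captured(self):
        (m,) = extract_size_mentions("不足 5CM")
        assert m.qualifier == "不足"
        (m,) = extract_size_mentions("大小约1.3CM × 1.7CM")
        assert m.qualifier == "约"

    @pytest.mark.parametrize("text", ["2018年3月4日复查", "第1、2组", "T4水平", "37.5度"])
    def test_non_size_numbers_rejected(self, text):
        assert extract_size_mentions(text) == []

    def test_raw_equals_span_substring(self, worked_size_sentence):
        sent = split_sentences(Document("d", worked_size_sentence))[0]
        for m in extract_size_mentions(sent):
            assert sent.text[m.start:m.end] == m.raw
            assert all(d.value > 0 for d in m.dimensions)
            assert 1 <= len(m.dimensions) <= 3

    def test_oracle_equivalence_on_generated_strings(self):
        rng = random.Random(20240915)
        for _ in range(1000):
            text = _random_size_text(rng)
            impl = [(m.start, m.end) for m in extract_size_mentions(text)]
            assert impl == brute_force_size_spans(text), text


class TestNormalizeSize:
    def test_unit_propagation(self):
        (m,) = extract_size_mentions("5x4x3CM")
        assert normalize_size(m, policy="propagate") == "5CMx4CMx3CM"
        assert normalize_size(m, policy="as_parsed") == "5x4x3CM"

    def test_single_dimension(self):
        (m,) = extract_size_mentions("约5CM")
        assert normalize_size(m) == "5CM"

    def test_normalize_then_parse_is_fixed_point(self):
        rng = random.Random(7)
        from onconer import gen_size_string
        for _ in range(200):
            surface, _ = gen_size_string(rng)
            (m,) = extract_size_mentions(surface)
            canon = normalize_size(m)
            (m2,) = extract_size_mentions(canon)
            assert normalize_size(m2) == canon
            assert [d.value for d in m2.dimensions] == [d.value for d in m.dimensions]


class TestDetectAndFilter:
    def test_detect_keeps_size_sentence_only(self, worked_size_sentence, lexicon):
        doc = Document("d", worked_size_sentence + "双侧胸膜未见增厚。2018年复查。")
        kept = detect_size_sentences(doc)
        assert len(kept) == 1 and "1.3CM" in kept[0].text

    def test_variant_of_primary_site_matches(self, lexicon):
        doc = Document("d", "左侧肺门见高密度影,大小约2CM×3CM。")
        sentences = detect_size_sentences(doc)
        assert filter_primary_related(sentences, ["左肺门"], lexicon) == sentences

    def test_unrelated_sentence_dropped(self, lexicon):
        doc = Document("d", "肝内低密度影,大小约2CM×3CM。")
        sentences = detect_size_sentences(doc)
        assert filter_primary_related(sentences, ["肺"], lexicon) == []

    def test_no_primary_sites_empty(self, lexicon):
        doc = Document("d", "左肺门见高密度影,大小约2CM×3CM。")
        assert filter_primary_related(detect_size_sentences(doc), [], lexicon) == []

    def test_density_sentences_rank_first(self, lexicon):
        doc = Document("d", "左肺门病灶约2CM。左肺门见高密度影,大小约3CM×4CM。")
        ranked = filter_primary_related(detect_size_sentences(doc), ["左肺门"], lexicon)
        assert "高密度影" in ranked[0].text


class TestFullPipeline:
    def test_worked_sentence_end_to_end(self, worked_size_sentence, lexicon):
        doc = Document("d", worked_size_sentence)
        mentions = extract_primary_sizes(doc, ["左肺上叶"], lexicon)
        assert [normalize_size(m) for m in mentions] == ["1.3CMx1.7CM"]
        assert [(d.value, d.unit) for d in mentions[0].dimensions] == [(1.3, "cm"), (1.7, "cm")]

    def test_size_in_metastasis_only_context_excluded(self, lexicon):
        doc = Document("d", "右乳见肿块,考虑乳癌。肝内转移灶大小约2CM×3CM。")
        primaries = extract_primary_sites(doc, lexicon)
        assert [m.normalized for m in primaries] == ["右乳"]
        assert extract_primary_sizes(doc, primaries, lexicon) == []

    def test_duplicate_sizes_collapse(self, lexicon):
        doc = Document("d", "左肺门见高密度影,大小约2CM×3CM。左侧肺门病灶约2CMx3CM。")
        mentions = extract_primary_sizes(doc, ["左肺门"], lexicon)
        assert [normalize_size(m) for m in mentions] == ["2CMx3CM"]
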
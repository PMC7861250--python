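"""Anatomy dictionary and keyword sets driving the extraction rules.

The extractors are entirely lexicon-driven: malignancy indicators select
candidate sentences for the primary site, density indicators rank size
sentences, metastasis keywords select key sentences, descriptor terms are
stripped from anatomic phrases, and conjunction tokens drive
coordination-ellipsis completion.  A curated seed lexicon covering the
lung / breast / lymph-node / mediastinum / liver / bone vocabulary of
thoracic oncology reports ships with the package; coverage is a data
concern and the lexicon is fully user-replaceable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

from .text_prep import SENTENCE_DELIMITERS, fold_for_match

CATEGORIES = ("anatomy", "malignancy", "density", "metastasis", "descriptor", "conjunction")

#: laterality prefixes, longest first so 左侧 wins over 左
LATERALITY_PREFIXES = ("左侧", "右侧", "左", "右")


class LexiconError(ValueError):
    """Raised for malformed or incomplete lexicon files."""


@dataclass(frozen=True)
class SiteTerm:
    """An anatomy surface string with its canonical (laterality-folded) form."""

    surface: str
    canonical: str
    laterality_marker: str | None = None

    @classmethod
    def from_surface(cls, surface: str) -> "SiteTerm":
        marker = _laterality_marker(surface)
        return cls(surface=surface, canonical=canonical_site(surface), laterality_marker=marker)


def _laterality_marker(site: str) -> str | None:
    for prefix in LATERALITY_PREFIXES:
        if site.startswith(prefix) and len(site) > len(prefix):
            return prefix
    return None


def canonical_site(site: str) -> str:
    """Deterministic normal form of a site: width/case folded, 左侧→左, 右侧→右.

    Laterality spelling variants (左肺门 / 左侧肺门) share one canonical form;
    distinct sites never collide.
    """
    folded = fold_for_match(site)
    if folded.startswith("左侧") and len(folded) > 2:
        return "左" + folded[2:]
    if folded.startswith("右侧") and len(folded) > 2:
        return "右" + folded[2:]
    return folded


def expand_site_variants(site: str) -> set[str]:
    """The site plus its 侧-insertion/deletion laterality variants.

    左X ↔ 左侧X and 右X ↔ 右侧X; sites without a laterality prefix are
    returned unchanged.  No other rewriting is performed.
    """
    if not site:
        raise ValueError("site must be non-empty")
    variants = {site}
    if site.startswith("左侧") and len(site) > 2:
        variants.add("左" + site[2:])
    elif site.startswith("右侧") and len(site) > 2:
        variants.add("右" + site[2:])
    elif site.startswith("左") and len(site) > 1:
        variants.add("左侧" + site[1:])
    elif site.startswith("右") and len(site) > 1:
        variants.add("右侧" + site[1:])
    return variants


def is_part_of(specific: str, approximate: str) -> bool:
    """True iff ``specific`` names a proper part of ``approximate``.

    Implemented as substring containment of the approximate site (or a
    laterality variant / laterality-stripped form of it) in the specific
    site, e.g. 左肺上叶 is a part of 肺.  Laterality spelling variants of the
    same site (左乳 vs 左侧乳) are NOT parts of each other.
    """
    if not specific or not approximate:
        raise ValueError("both site strings must be non-empty")
    spec_c = canonical_site(specific)
    approx_c = canonical_site(approximate)
    if spec_c == approx_c:
        return False
    forms = {approx_c}
    marker = _laterality_marker(approx_c)
    if marker:
        forms.add(approx_c[len(marker):])
    # proper containment only: the de-lateralized approximate equalling the
    # specific (乳 vs 右乳) means MORE general, not a part
    return any(form and form != spec_c and form in spec_c for form in forms)


@dataclass
class Lexicon:
    """All term sets used by the extraction rules."""

    anatomy_terms: set[str]
    malignancy_indicators: set[str]
    density_indicators: set[str]
    metastasis_keywords: set[str]
    descriptor_terms: set[str]
    conjunction_tokens: tuple[str, ...]

    _term_table: dict[str, str] | None = field(default=None, repr=False, compare=False)
    _max_term_len: int = field(default=0, repr=False, compare=False)
    _anatomy_folded: set[str] = field(default_factory=set, repr=False, compare=False)
    _descriptor_folded: set[str] = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._validate()
        self._build_tables()

    def _validate(self) -> None:
        for name in ("anatomy_terms", "malignancy_indicators", "density_indicators",
                     "metastasis_keywords", "descriptor_terms"):
            if not getattr(self, name):
                raise LexiconError(f"required category empty: {name}")
        if not self.conjunction_tokens:
            raise LexiconError("required category empty: conjunction_tokens")
        for term in self.anatomy_terms:
            if not term or any(c in SENTENCE_DELIMITERS for c in term):
                raise LexiconError(f"invalid anatomy term: {term!r}")

    def _build_tables(self) -> None:
        # anatomy matching includes auto-generated laterality variants so
        # that e.g. 左肺上叶 matches whole when the lexicon lists 肺上叶
        anatomy_all: set[str] = set()
        for term in self.anatomy_terms:
            anatomy_all.update(expand_site_variants(term))
            if _laterality_marker(term) is None:
                for prefix in ("左", "右", "左侧", "右侧"):
                    anatomy_all.add(prefix + term)
        self._anatomy_folded = {fold_for_match(t) for t in anatomy_all}
        self._descriptor_folded = {fold_for_match(t) for t in self.descriptor_terms}
        table: dict[str, str] = {}
        for cat, terms in (
            ("conjunction", self.conjunction_tokens),
            ("metastasis", self.metastasis_keywords),
            ("malignancy", self.malignancy_indicators),
            ("density", self.density_indicators),
            ("descriptor", self.descriptor_terms),
            ("anatomy", anatomy_all),  # last: anatomy wins category ties
        ):
            for term in terms:
                table[fold_for_match(term)] = cat
        self._term_table = table
        self._max_term_len = max(len(t) for t in table)

    # -- queries ---------------------------------------------------------

    def term_table(self) -> tuple[dict[str, str], int]:
        """(folded term -> category, max term length) for the segmenter."""
        assert self._term_table is not None
        return self._term_table, self._max_term_len

    def is_anatomy(self, surface: str) -> bool:
        """Whether a surface string is an anatomy term or a laterality
        variant of one."""
        return fold_for_match(surface) in self._anatomy_folded

    def is_descriptor(self, surface: str) -> bool:
        return fold_for_match(surface) in self._descriptor_folded

    def contains_keyword(self, text: str, keywords: set[str]) -> bool:
        folded = fold_for_match(text)
        return any(fold_for_match(k) in folded for k in keywords)


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a two-column TSV file (term<TAB>category).

    Categories: anatomy, malignancy, density, metastasis, descriptor,
    conjunction.  ``#``-prefixed comment lines and blank lines are
    ignored; duplicate (term, category) rows collapse silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"lexicon file not found: {path}")
    buckets: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise LexiconError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(cols)}")
            term, category = cols[0].strip(), cols[1].strip()
            if not term:
                raise LexiconError(f"{path}:{lineno}: empty term")
            if category not in CATEGORIES:
                raise LexiconError(f"{path}:{lineno}: unknown category {category!r}")
            if (term, category) in seen:
                continue
            seen.add((term, category))
            buckets[category].append(term)
    missing = [c for c in CATEGORIES if not buckets[c]]
    if missing:
        raise LexiconError(f"{path}: required categories absent: {', '.join(missing)}")
    return Lexicon(
        anatomy_terms=set(buckets["anatomy"]),
        malignancy_indicators=set(buckets["malignancy"]),
        density_indicators=set(buckets["density"]),
        metastasis_keywords=set(buckets["metastasis"]),
        descriptor_terms=set(buckets["descriptor"]),
        conjunction_tokens=tuple(buckets["conjunction"]),
    )


def default_lexicon_path() -> Path:
    """Path of the packaged seed lexicon TSV."""
    return Path(str(importlib.resources.files("onconer").joinpath("data/default_lexicon.tsv")))


def load_default_lexicon() -> Lexicon:
    """Load the packaged seed lexicon."""
    return load_lexicon(default_lexicon_path())
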
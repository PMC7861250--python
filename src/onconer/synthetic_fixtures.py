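"""Synthetic Chinese diagnostic-report generator with gold annotations.

The original challenge corpus (600 training + 200 testing reports) is not
redistributable, so this module fabricates reports that emulate its
structure: multi-sentence documents with about one primary-site clause,
0.6 size clauses and 2.5 metastatic-site clauses per document on average,
assembled from sentence templates the extraction rules are designed for.

Gold annotations record the entities the method SHOULD return.  For the
adversarial knobs this means gold intentionally diverges from what the
rule set produces:

* ``compound`` documents contain a compound site phrase without a
  conjunction (右肺门纵隔多发肿大淋巴结); gold records the correctly split
  sites, which the faithfully reproduced rule set does not produce;
* ``unknown_anatomy`` documents plant a site absent from the lexicon;
* ``double_negation`` documents use 转移不除外, which the default
  substring policy handles correctly (tagged so tests can partition).

With every adversarial probability at zero, extraction recovers the gold
exactly (precision = recall = 1) by construction.

Templates are data (``data/templates.json``), not code, so sentence shapes
are user-extendable.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from importlib import resources
from typing import Any

from .lexicon import Lexicon, canonical_site, expand_site_variants, load_default_lexicon


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the report generator.

    Defaults emulate the challenge training-corpus statistics: one primary
    site per document, a size mention in 60% of documents, 0–5 metastatic
    sites (mean 2.5), 5–25 sentences.
    """

    n_docs: int = 100
    seed: int = 0
    sentences_per_doc: tuple[int, int] = (5, 25)
    p_size_mention: float = 0.6
    meta_sites_per_doc: tuple[int, int] = (0, 5)
    p_conjunction_list: float = 0.3
    p_double_negation: float = 0.05
    p_compound_no_conjunction: float = 0.05
    p_unknown_anatomy: float = 0.05
    p_refinement: float = 0.3
    p_site_variant: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_size_mention", "p_conjunction_list", "p_double_negation",
                     "p_compound_no_conjunction", "p_unknown_anatomy",
                     "p_refinement", "p_site_variant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("sentences_per_doc", "meta_sites_per_doc"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"{name} range empty or negative: {(lo, hi)}")
        if self.n_docs < 0:
            raise ValueError("n_docs must be >= 0")


def load_templates() -> dict[str, Any]:
    """Load the packaged sentence-template blocks."""
    text = resources.files("onconer").joinpath("data/templates.json").read_text(encoding="utf-8")
    return json.loads(text)


_SEPARATORS = ("x", "X", "×", "*")
_UNITS = ("CM", "MM", "cm", "mm")


def gen_size_string(rng: random.Random) -> tuple[str, str]:
    """Random in-grammar size expression.

    Returns ``(surface, normalized)`` where ``normalized`` is the
    canonical form under the default unit-propagation policy.  The last
    dimension always carries a unit; earlier dimensions carry one with
    probability 0.3.
    """
    n_dims = rng.choices((1, 2, 3), weights=(2, 5, 3))[0]
    sep = rng.choice(_SEPARATORS)
    last_unit = rng.choice(_UNITS)
    parts_surface, nums, units = [], [], []
    for i in range(n_dims):
        if rng.random() < 0.5:
            num = str(rng.randint(1, 9))
        else:
            num = f"{rng.randint(0, 9)}.{rng.randint(1, 9)}"
        nums.append(num)
        if i == n_dims - 1:
            unit = last_unit
        else:
            unit = rng.choice(_UNITS) if rng.random() < 0.3 else ""
        units.append(unit)
        parts_surface.append(num + unit)
    surface = sep.join(parts_surface)
    fill = last_unit.upper()
    normalized = "x".join(
        num + (unit.upper() if unit else fill) for num, unit in zip(nums, units))
    return surface, normalized


class _DocBuilder:
    """Assembles one synthetic document with its gold record and tags."""

    def __init__(self, rng: random.Random, templates: dict[str, Any], config: GeneratorConfig):
        self.rng = rng
        self.t = templates
        self.cfg = config
        self.core: list[str] = []
        self.gold_primary: list[str] = []
        self.gold_sizes: list[str] = []
        self.gold_meta: list[str] = []
        self.tags: list[str] = []
        self._used: set[str] = set()

    def _claim(self, entity: str) -> bool:
        key = canonical_site(entity)
        if key in self._used:
            return False
        self._used.add(key)
        return True

    # -- clause builders -------------------------------------------------

    def primary_clause(self) -> str:
        rng, t = self.rng, self.t
        specific, organ = rng.choice(t["primary_sites"])
        if organ and rng.random() < self.cfg.p_refinement:
            self.core.append(organ + rng.choice(t["postop_phrases"]) + "。")
            self.core.append(specific + rng.choice(t["specific_lesion_phrases"]) + "。")
        else:
            self.core.append(
                specific + rng.choice(t["lesion_phrases"]) + ","
                + rng.choice(t["malignancy_phrases"]) + "。")
        self.gold_primary.append(specific)
        self._claim(specific)
        return specific

    def size_clause(self, primary: str) -> None:
        rng, t = self.rng, self.t
        form = primary
        if rng.random() < self.cfg.p_site_variant:
            variants = sorted(expand_site_variants(primary) - {primary})
            if variants:
                form = rng.choice(variants)
        surface, normalized = gen_size_string(rng)
        lead = rng.choice(("大小约", "大小", "范围约"))
        self.core.append(
            form + "见" + rng.choice(t["size_densities"]) + "," + lead + surface + "。")
        self.gold_sizes.append(normalized)

    def lymph_clause(self) -> int:
        rng, t = self.rng, self.t
        for _ in range(20):
            region = rng.choice(t["meta_lymph_regions"])
            inner = "内" if region in ("纵隔", "盆腔", "腹腔") else ""
            entity = region + inner + "淋巴结"
            if self._claim(entity):
                break
        else:
            return 0
        desc = rng.choice(t["pad_descriptors"])
        self.core.append(region + inner + desc + "淋巴结," + rng.choice(t["metastasis_cues"]) + "。")
        self.gold_meta.append(entity)
        return 1

    def organ_clause(self) -> int:
        rng, t = self.rng, self.t
        for _ in range(20):
            organ = rng.choice(t["meta_organs"])
            if self._claim(organ):
                break
        else:
            return 0
        inner = "内" if organ in ("肝", "脑", "脾") else ""
        self.core.append(
            organ + inner + rng.choice(t["pad_descriptors"]) + "结节,"
            + rng.choice(t["metastasis_cues"]) + "。")
        self.gold_meta.append(organ)
        return 1

    def conjunction_clause(self) -> int:
        rng, t = self.rng, self.t
        for _ in range(20):
            h1, h2 = rng.sample(t["conjunction_heads"], 2)
            e1, e2 = h1 + "淋巴结", h2 + "淋巴结"
            if canonical_site(e1) not in self._used and canonical_site(e2) not in self._used:
                self._claim(e1)
                self._claim(e2)
                break
        else:
            return 0
        conj = rng.choice(("、", "及", "与"))
        desc = rng.choice(t["pad_descriptors"])
        self.core.append(desc + h1 + conj + h2 + "淋巴结," + rng.choice(t["metastasis_cues"]) + "。")
        self.gold_meta.extend([e1, e2])
        return 2

    def compound_clause(self) -> int:
        rng, t = self.rng, self.t
        h1, h2 = rng.choice(t["compound_pairs"])
        e1, e2 = h1 + "淋巴结", h2 + "淋巴结"
        if canonical_site(e1) in self._used or canonical_site(e2) in self._used:
            return 0
        self._claim(e1)
        self._claim(e2)
        self.core.append(h1 + h2 + "多发肿大淋巴结," + rng.choice(t["metastasis_cues"]) + "。")
        self.gold_meta.extend([e1, e2])
        self.tags.append("compound")
        return 2

    def double_negation_clause(self) -> int:
        rng, t = self.rng, self.t
        for _ in range(20):
            site = rng.choice(t["double_negation_sites"])
            if self._claim(site):
                break
        else:
            return 0
        self.core.append(site + "多发可疑小结节,转移不除外。")
        self.gold_meta.append(site)
        self.tags.append("double_negation")
        return 1

    def unknown_clause(self) -> int:
        rng, t = self.rng, self.t
        site = rng.choice(t["unknown_sites"])
        if not self._claim(site):
            return 0
        self.core.append(site + "多发结节,考虑转移。")
        self.gold_meta.append(site)
        self.tags.append("unknown_anatomy")
        return 1

    # -- assembly ----------------------------------------------------------

    def build(self, doc_id: str) -> tuple[dict, dict, dict]:
        rng, cfg = self.rng, self.cfg
        primary = self.primary_clause()
        if rng.random() < cfg.p_size_mention:
            self.size_clause(primary)
        k_meta = rng.randint(*cfg.meta_sites_per_doc)
        planted = 0
        if rng.random() < cfg.p_compound_no_conjunction:
            planted += self.compound_clause()
        if rng.random() < cfg.p_double_negation:
            planted += self.double_negation_clause()
        if rng.random() < cfg.p_unknown_anatomy:
            planted += self.unknown_clause()
        while planted < k_meta:
            remaining = k_meta - planted
            if remaining >= 2 and rng.random() < cfg.p_conjunction_list:
                added = self.conjunction_clause()
            elif rng.random() < 0.5:
                added = self.lymph_clause()
            else:
                added = self.organ_clause()
            if added == 0:
                break  # pools exhausted for this document
            planted += added
        # pad with inert filler sentences and interleave
        target = rng.randint(*cfg.sentences_per_doc)
        sentences = list(self.core)
        while len(sentences) < target:
            filler = rng.choice(self.t["fillers"])
            sentences.insert(rng.randint(0, len(sentences)), filler)
        text = "".join(sentences)
        doc = {"id": doc_id, "text": text}
        gold = {
            "id": doc_id,
            "primary_sites": list(self.gold_primary),
            "primary_sizes": list(self.gold_sizes),
            "metastatic_sites": list(self.gold_meta),
        }
        prov = {"id": doc_id, "tags": sorted(set(self.tags))}
        return doc, gold, prov


def generate_corpus(config: GeneratorConfig, lexicon: Lexicon | None = None,
                    ) -> tuple[list[dict], list[dict], list[dict]]:
    """Generate a corpus of synthetic reports with gold and provenance tags.

    Deterministic given the config (which carries the seed).  Returns
    ``(documents, gold, provenance)`` as lists of JSON-serialisable dicts
    in the JSON-lines shapes the extract and evaluate commands consume.
    """
    lexicon = lexicon or load_default_lexicon()
    templates = load_templates()
    _check_templates(templates, lexicon)
    rng = random.Random(config.seed)
    docs, golds, provs = [], [], []
    for i in range(config.n_docs):
        builder = _DocBuilder(rng, templates, config)
        doc, gold, prov = builder.build(f"syn-{i:04d}")
        docs.append(doc)
        golds.append(gold)
        provs.append(prov)
    return docs, golds, provs


def _check_templates(templates: dict[str, Any], lexicon: Lexicon) -> None:
    """Planted sites must be known to the lexicon (except the deliberately
    unknown pool), otherwise in-grammar recall guarantees break."""
    for specific, organ in templates["primary_sites"]:
        if not lexicon.is_anatomy(specific):
            raise ValueError(f"template primary site not in lexicon: {specific}")
        if organ and not lexicon.is_anatomy(organ):
            raise ValueError(f"template organ not in lexicon: {organ}")
    for key in ("meta_lymph_regions", "meta_organs", "conjunction_heads", "double_negation_sites"):
        for term in templates[key]:
            if not lexicon.is_anatomy(term):
                raise ValueError(f"template site not in lexicon: {term}")
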
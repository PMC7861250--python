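# Methods

## Scope and assumptions

`onconer` extracts three entity types from Chinese diagnostic-imaging
conclusions: primary tumor sites, primary tumor size expressions, and
metastatic tumor sites. The approach is deliberately rule-based: the task
has little training data, the target expressions are strongly patterned,
and every decision must be auditable. The core assumptions are

* entities and their indicator keywords co-occur **within one sentence**;
* a report usually has **one** primary tumor site, and it is the first
  malignancy-associated anatomic mention in reading order;
* size expressions follow a closed grammar;
* metastatic sites appear in sentences containing a metastasis keyword.

All matching is exact and lexicon-driven. Coverage of the anatomy
dictionary is therefore a *data* concern: the shipped seed lexicon
(~130 base anatomy terms centred on thoracic oncology, plus keyword sets)
is a starting point and fully user-replaceable via `--lexicon`.

## Text preparation

Sentences are split on 。；;！？ and newline; a delimiter run attaches to
the preceding sentence and spans reconstruct the document exactly. Commas
(both , and ，) do **not** split, because size statements routinely
continue across them ("…密度灶,大小约1.3CM × 1.7CM,边缘分叶…").
A document consisting only of delimiters is kept as one degenerate
sentence rather than silently dropped.

Full-width ASCII variants are folded to ASCII and Latin letters are
upper-cased **for matching only** (ＭＴ ≡ MT ≡ mt, ｃｍ ≡ CM); both folds
are one-to-one per code point, so offsets in the folded text index the
original surface, which is preserved in all output spans.

Tokenization is greedy longest-match against the lexicon (anatomy terms —
including automatically generated laterality variants 左/右/左侧/右侧 +
term — keywords, descriptors, conjunctions); unmatched characters group
into maximal runs. The tokenizer contract is only that lexicon terms
surface unbroken and that token concatenation reproduces the input; any
segmenter honouring that contract can be substituted.

Descriptor stripping removes appearance wording (多发肿大, 小, 散在 …)
from anatomic phrases. It is tokenization-aware so that descriptors
embedded in longer dictionary terms survive (小 inside 小肠), and iterates
to a fixed point, making it idempotent.

## Primary site

Pipeline: sentences with a malignancy indicator (癌 恶性 瘤 MT CA) →
drop sentences containing any metastasis keyword (the primary site must
not be metastasis-related; the keyword set is the mechanism) → anatomy
matching → first mention in document order (leftmost wins within a
sentence) → refinement. Refinement scans the whole document, skipping
metastasis sentences by default (`refine_skip_metastasis`), for the first
anatomy mention that is a *proper part* of the approximate site.

Part-of is substring containment of the approximate site (or its
laterality-stripped form) in the specific site — the smallest mechanism
consistent with the motivating case 肺 ⊂ 左肺上叶. Two guards matter:

* laterality spelling variants of one site (左乳 / 左侧乳) share a
  canonical form and are **not** parts of each other, otherwise
  refinement would "refine" a site to its own spelling variant;
* the containment must be proper: 乳 is more general than 右乳, not a
  part of it, so the de-lateralized form may not equal the specific site.

Multi-primary reports are handled the way the rule set defines: one site
is returned and the second is missed (a documented, reproduced error).
`multi_primary=True` returns the first site of *every* surviving
malignancy sentence — an extension beyond the reference behaviour, off by
default. Long compound sites absent from the dictionary decay to their
covered tail (胸下段食管 → 食管); this is a lexicon-coverage issue, fixable
by adding the compound term to the TSV, and is deliberately not patched in
code.

## Tumor size

Size expressions form a small closed language, specified here as a
grammar rather than one monolithic regex: per dimension an integer or decimal number with an
optional unit (CM or MM, any case/width); 1–3 dimensions joined by ×, X,
x or * with optional surrounding whitespace; an optional qualifier 约 or
不足 (with optional 大小 prefix). A match must contain **at least one
explicit unit**, which keeps dates and other bare-number runs out. DM is
not a unit radiologists use for lesion measurements and is not accepted.
Matching is
leftmost-longest and non-overlapping.

Primary-relatedness: a size sentence is kept iff it contains a laterality
variant (侧-insertion/deletion, e.g. 左肺门 ↔ 左侧肺门) of a primary site
or is the primary-site sentence itself; among survivors, sentences with a
density indicator (高密度影, 低密度影, 不规则团块 …) rank first. With no
primary site the size task returns nothing, matching the task definition.
Variant expansion is restricted to the 侧 pattern — no fuzzy matching —
and a config switch controls whether it also applies elsewhere.

Normalization joins dimensions with a lowercase `x` and uppercase units;
under the default `propagate` policy unit-less dimensions inherit the last
explicit unit (`5x4x3CM → 5CMx4CMx3CM`). Parsing, normalizing and
re-parsing is a fixed point (tested). Duplicates collapse on the
normalized string, since gold answers are surface strings. Units are
never converted between cm and mm.

## Metastatic sites

Key sentences contain a metastasis keyword by plain substring matching.
This intentionally treats the double negative 转移不除外 ("metastasis not
excluded") as a positive mention — the desired reading. The alternative
`negation_policy="drop-negated"` drops sentences with single-negated
metastasis (未见/无…转移) unless a double-negative cue (不除外, 待排) is
present; the default is the substring policy.

Within a key sentence, anatomy-bearing noun phrases are maximal contiguous
runs of anatomy terms, descriptor terms, conjunction tokens and locative
characters (内 部 旁), truncated at the run's last anatomy token (so
trailing descriptors never leak) and required to contain at least one
anatomy term. Punctuation and any other token terminates a run. The whole
key sentence is scanned, not just the span before the keyword. This
phrase-boundary rule is the genuinely open design point of the method;
the rule chosen is the simplest one satisfying every motivating example.

Coordination-ellipsis completion splits a phrase on 、 及 与, identifies
the shared suffix as the longest lexicon anatomy term that is a *proper*
suffix of the last conjunct (fallback: its trailing token), and appends it
to every conjunct not already ending with it. When the identified suffix
is the entire last conjunct (肺、肝 — a plain list, nothing elided) the
conjuncts are returned unchanged. The proper-suffix restriction is why
the seed lexicon lists the bare head 淋巴结 rather than compounds like
纵隔淋巴结: a compound entry would make itself the "shared suffix" and
corrupt completion, while segmentation covers the compound surface anyway.
Compound phrases *without* a conjunction (右肺门纵隔多发肿大淋巴结) are
emitted un-split — a reproduced, documented error of the rule set.
Duplicates fold across the document on the laterality-normalized form.

## Evaluation

Exact matching of normalized strings with set semantics per document;
TP/FP/FN pooled over documents (micro averaging, the convention for
entity-level P/R/F1; macro available by flag). Conventions: TP+FP = 0 gives precision 0, TP+FN = 0 gives recall
0, and an evaluation where *every* document is empty on both sides scores
1 (vacuous perfection). TN is never computed: extraction has no closed
universe of negatives and the three formulas never use it.

Weighted overall: weights 0.2 / 0.3 / 0.5 (primary / size / metastatic).
Weighting can act on the per-task metrics or on the underlying counts, and
the two disagree in general; both modes ship (`metric` — dot product of
the per-task metrics, the default — and `count` — weight-scaled counts
with the formulas re-applied).

The robustness experiment draws, for each subsample size (the original
design: 20…200 step 20, 50 repeats), uniform random document subsets
without replacement, scores the weighted overall on each, and reports
mean and population standard deviation. Repeats at full corpus size draw
identical subsets; the std is reported as exactly zero there (float
summation noise is clamped).

## Synthetic corpus

The generator emulates the structure of the original corpus, not its
language. Defaults mirror the reference training profile: one primary
clause per document (reference mean 1.02), a size clause with probability
0.6 (0.60), 0–5 metastatic sites drawn uniformly (mean 2.5 vs 2.46), and
5–25 sentences per document (reference means 14.0 training / 24.7
testing). Adversarial probabilities default to 0.05 each — the error
cases are occasional in real data and no rates are published. Sentence
shapes live in `data/templates.json`, so users can extend them without
touching code.

Each document is assembled from: a primary clause (optionally split into
an approximate organ sentence and a specific-site sentence, probability
0.3, exercising refinement), an optional size clause using a laterality
variant of the primary site (variant probability 0.5), metastasis clauses
(single sites, conjunction lists with probability 0.3, plus the tagged
adversarial cases), and inert filler sentences (no indicators, no digits)
interleaved at random positions that never permute the core clause order.
Planted entities are kept canonically distinct within a document.

Gold records what the method *should* return. For `compound` and
`unknown_anatomy` documents that is deliberately more than the rules can
produce, so recall on those partitions is below 1 by design;
`double_negation` documents are handled correctly by the default policy
and are tagged only so tests can partition them. With all three
adversarial probabilities at zero every gold entity is recoverable, and
extraction achieves precision = recall = 1 on all three tasks — this is a
property of the generator/extractor pair, and says nothing about recall
on real clinical text, where dictionary coverage, abbreviations (T4胸椎),
compound sites and richer negation dominate the error budget.

Determinism: one `random.Random(seed)` drives everything; identical
config yields byte-identical output.

## Numerical and design choices

* Problem sizes in the shipped checks — 200 documents for the end-to-end
  recovery run, 600 for the density profile, 1,000 strings for the
  matcher/oracle comparison — are large enough for stable statistics while
  keeping the whole suite under a few seconds.
* Seeds are fixed everywhere randomness exists (generator, subsampling,
  string fuzzing); the acceptance script threads a single `--seed` through
  all of them.
* Tie-breaks: leftmost mention wins within a sentence; first-seen surface
  wins within a canonical dedup group; anatomy wins category ties in the
  segmentation table.
* Degenerate inputs: empty text → no sentences; empty primary-site list →
  no sizes; documents with no indicators → empty predictions; empty
  pred/gold everywhere → vacuous perfect score.

## Known limitations

* No abbreviation resolution (T4胸椎 is not recognized as one entity).
* Compound anatomic phrases lacking conjunctions are not split.
* No concept normalization to external terminologies (UMLS/MeSH).
* Matching is exact; there is no partial-credit or overlap-based scoring.
* The seed lexicon is a curated starting point, not an exhaustive
  anatomy dictionary; real-world recall depends on extending it.
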
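# onconer

Pattern-based extraction of tumor-related entities from unstructured
Chinese diagnostic-imaging text (radiology report conclusions), with an
entity-level weighted evaluation scheme and a synthetic-report generator.

## The problem

Chinese radiology reports describe cancers in free text. Three kinds of
structured facts are routinely needed downstream:

* **primary tumor site** — the first anatomic site mentioned in the report
  that is associated with a malignancy description (癌, 恶性, 瘤, MT, CA)
  and not with metastasis, e.g. 左肺上叶 (superior lobe of left lung);
* **primary tumor size** — measurement expressions such as `1.3CM × 1.7CM`,
  `5x4x3CM` or `不足 5CM`;
* **metastatic sites** — anatomic positions co-occurring with
  metastasis-indicating keywords (转移, 考虑转移, 多发转移).

`onconer` implements a rule-based pipeline for all three tasks. It is
entirely lexicon-driven — anatomy dictionary, malignancy/density/metastasis
keyword sets, descriptor terms and conjunction tokens ship as a replaceable
TSV file — and deterministic: identical input and configuration always
produce identical output.

## The method

1. **Text preparation.** Reports are split into sentences on 。；;！？ and
   newline (commas do not split: size statements continue across them).
   Sentences are tokenized by greedy longest-match against the lexicon, so
   every dictionary term surfaces as one unbroken token. Full-width ASCII
   is folded and Latin matching is case-insensitive.
2. **Primary site.** Keep sentences containing a malignancy indicator, drop
   those containing a metastasis keyword, match anatomy terms, take the
   first mention in document order, then *refine*: if a more specific site
   elsewhere in the report contains the approximate site as a substring
   (左肺上叶 ⊃ 肺), it replaces it.
3. **Tumor size.** Detect sentences matching the size grammar (1–3 decimal
   dimensions, optional CM/MM units with at least one unit required,
   separators × X x *, qualifiers 约/不足), keep only sentences containing a
   laterality variant (左肺门 ↔ 左侧肺门) of a primary site, then parse all
   leftmost-longest matches. Output is normalized, e.g. `1.3CMx1.7CM`,
   with the trailing unit propagated to unit-less dimensions
   (`5x4x3CM → 5CMx4CMx3CM`).
4. **Metastatic sites.** In sentences containing a metastasis keyword,
   anatomy-bearing noun phrases are located, descriptive wording is
   stripped (纵隔内多发肿大淋巴结 → 纵隔内淋巴结), and coordination ellipsis
   is completed: a head noun elided from all but the last conjunct is
   restored (肺门及前纵隔淋巴结 → 肺门淋巴结, 前纵隔淋巴结).

**Evaluation.** Predictions are matched to gold annotations by exact
normalized string. With TP/FP/FN pooled over documents,

    P = TP/(TP+FP),  R = TP/(TP+FN),  F1 = 2PR/(P+R),

and the three task scores combine with weights 0.2 (primary site),
0.3 (size), 0.5 (metastatic site). A robustness experiment rescoring
random document subsamples of increasing size is included.

**Synthetic corpus.** Because the original challenge corpus is not
redistributable, `onconer` generates synthetic reports with gold
annotations that emulate its structure (≈1 primary site, 0.6 size
mentions, 2.5 metastatic sites per document), including tagged adversarial
cases (compound phrases without conjunctions, out-of-lexicon sites, double
negations) that reproduce the method's documented failure modes.

## Worked example

```python
from onconer import Document, load_default_lexicon, extract_document

lexicon = load_default_lexicon()
report = Document("r001", (
    "肺癌术后改变。"
    "左肺上叶示一不规则软组织密度灶,大小约1.3CM × 1.7CM,边缘分叶,可见强化。"
    "肺门及前纵隔淋巴结,考虑多发转移。"
    "肝内多发结节,考虑转移。"
))
print(extract_document(report, lexicon))
```

prints

```python
{'id': 'r001', 'primary_sites': ['左肺上叶'], 'primary_sizes': ['1.3CMx1.7CM'],
 'metastatic_sites': ['肺门淋巴结', '前纵隔淋巴结', '肝']}
```

The approximate primary site 肺 (from 肺癌) was refined to 左肺上叶; the
size expression was parsed from the sentence containing that site and
normalized; the coordinated lymph-node phrase was completed into two
entities, and 肝 was picked up from its own metastasis sentence.

The same pipeline is available from the shell:

```bash
onconer gen-fixtures --n 200 --seed 42 --out fixtures/
onconer extract  --input fixtures/docs.jsonl --output pred.jsonl
onconer evaluate --pred pred.jsonl --gold fixtures/gold.jsonl \
                 --robustness 20:200:20 --repeats 50 --seed 1
```

## Layout

- `src/onconer/lexicon.py` — term sets, laterality variants, part-of reasoning
- `src/onconer/text_prep.py` — sentences, tokenization, descriptor stripping
- `src/onconer/primary_site.py` / `tumor_size.py` / `metastasis.py` — the three extractors
- `src/onconer/evaluation.py` — entity-level P/R/F1, weighted overall, robustness
- `src/onconer/synthetic_fixtures.py` — synthetic corpus generator
- `src/onconer/pipeline.py`, `cli.py` — JSON-lines I/O and the `onconer` command
- `src/onconer/data/` — seed lexicon (TSV) and sentence templates (JSON)
- `docs/methods.md` — modelling notes, parameter choices, limitations
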
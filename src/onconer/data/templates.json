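{
  "comment": "Sentence-building blocks for the synthetic report generator. Synthetic stand-in corpus: the real challenge reports are not redistributable; these templates emulate only the structures the extraction rules depend on.",
  "primary_sites": [
    ["左肺上叶", "肺"],
    ["右肺上叶", "肺"],
    ["左肺下叶", "肺"],
    ["右肺下叶", "肺"],
    ["右肺中叶", "肺"],
    ["左肺门", "肺"],
    ["右乳", "乳"],
    ["左乳", "乳"],
    ["右乳腺", "乳腺"],
    ["左乳腺", "乳腺"],
    ["食管", null],
    ["胃", null],
    ["直肠", null],
    ["甲状腺", null],
    ["肝右叶", "肝"],
    ["左肾", null]
  ],
  "malignancy_phrases": [
    "考虑恶性病变",
    "恶性肿瘤可能",
    "考虑为原发性MT可能",
    "考虑CA",
    "考虑恶性可能性大"
  ],
  "lesion_phrases": [
    "见不规则肿块影",
    "可见不规则团块",
    "见占位",
    "见分叶状肿块影"
  ],
  "postop_phrases": [
    "癌术后改变",
    "癌术后",
    "恶性肿瘤术后复查"
  ],
  "specific_lesion_phrases": [
    "见软组织密度灶,边缘分叶",
    "见不规则结节影,边界欠清",
    "可见团块影,形态欠规则"
  ],
  "size_densities": [
    "高密度影",
    "低密度影",
    "不规则团块",
    "软组织密度灶"
  ],
  "meta_lymph_regions": [
    "纵隔",
    "盆腔",
    "腹腔",
    "腹膜后",
    "颈部",
    "腋窝"
  ],
  "meta_organs": [
    "肝",
    "脑",
    "肾上腺",
    "胸膜",
    "脾",
    "骶骨",
    "腰椎",
    "颅骨",
    "髂骨"
  ],
  "conjunction_heads": [
    "肺门",
    "前纵隔",
    "后纵隔",
    "颈部",
    "腋窝",
    "腹膜后",
    "锁骨上窝"
  ],
  "pad_descriptors": [
    "多发肿大",
    "多发",
    "肿大",
    "散在"
  ],
  "metastasis_cues": [
    "考虑转移",
    "考虑多发转移",
    "转移可能"
  ],
  "compound_pairs": [
    ["右肺门", "纵隔"],
    ["左肺门", "前纵隔"],
    ["右肺门", "后纵隔"]
  ],
  "double_negation_sites": [
    "左肺",
    "右肺",
    "肝"
  ],
  "unknown_sites": [
    "胃体部",
    "胰尾",
    "骶前间隙"
  ],
  "fillers": [
    "余未见特殊。",
    "建议结合临床随访复查。",
    "扫描所见未见明显异常。",
    "增强后未见异常强化。",
    "所示骨质未见明显破坏。",
    "气管居中,管腔通畅。",
    "请结合临床及其他检查。",
    "双侧对称,未见明显异常征象。"
  ]
}
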
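# Seed lexicon: term<TAB>category
# Categories: anatomy, malignancy, density, metastasis, descriptor, conjunction
# Anatomy coverage targets thoracic-oncology reporting (lung/breast plus the
# common metastatic beds: lymph nodes, mediastinum, liver, bone, brain).
# Laterality variants (左/右/左侧/右侧 + term) are generated automatically.
肺	anatomy
肺门	anatomy
肺尖	anatomy
肺叶	anatomy
肺上叶	anatomy
肺中叶	anatomy
肺下叶	anatomy
肺舌叶	anatomy
支气管	anatomy
主支气管	anatomy
气管	anatomy
气管隆突	anatomy
纵隔	anatomy
前纵隔	anatomy
后纵隔	anatomy
上纵隔	anatomy
中纵隔	anatomy
胸膜	anatomy
胸壁	anatomy
胸腔	anatomy
胸骨	anatomy
胸椎	anatomy
肋骨	anatomy
锁骨	anatomy
锁骨上窝	anatomy
锁骨上区	anatomy
腋窝	anatomy
腋下	anatomy
乳	anatomy
乳腺	anatomy
乳房	anatomy
乳头	anatomy
淋巴结	anatomy
肝	anatomy
肝门	anatomy
肝叶	anatomy
肝右叶	anatomy
肝左叶	anatomy
肝实质	anatomy
胆囊	anatomy
胆管	anatomy
胰	anatomy
胰腺	anatomy
脾	anatomy
胃	anatomy
胃窦	anatomy
贲门	anatomy
食管	anatomy
十二指肠	anatomy
小肠	anatomy
结肠	anatomy
升结肠	anatomy
横结肠	anatomy
降结肠	anatomy
乙状结肠	anatomy
直肠	anatomy
阑尾	anatomy
肾	anatomy
肾上腺	anatomy
肾盂	anatomy
输尿管	anatomy
膀胱	anatomy
前列腺	anatomy
精囊腺	anatomy
睾丸	anatomy
子宫	anatomy
宫颈	anatomy
卵巢	anatomy
附件区	anatomy
阴道	anatomy
腹膜	anatomy
腹膜后	anatomy
腹腔	anatomy
盆腔	anatomy
网膜	anatomy
大网膜	anatomy
肠系膜	anatomy
脑	anatomy
小脑	anatomy
大脑	anatomy
脑实质	anatomy
额叶	anatomy
顶叶	anatomy
颞叶	anatomy
枕叶	anatomy
脑膜	anatomy
颅骨	anatomy
头皮	anatomy
眼眶	anatomy
鼻咽	anatomy
口咽	anatomy
喉	anatomy
舌	anatomy
扁桃体	anatomy
腮腺	anatomy
颌下腺	anatomy
甲状腺	anatomy
颈部	anatomy
上颌窦	anatomy
筛窦	anatomy
额窦	anatomy
蝶窦	anatomy
骨	anatomy
骨盆	anatomy
脊柱	anatomy
颈椎	anatomy
腰椎	anatomy
骶骨	anatomy
骶椎	anatomy
髂骨	anatomy
耻骨	anatomy
坐骨	anatomy
股骨	anatomy
股骨头	anatomy
肱骨	anatomy
肱骨头	anatomy
肩胛骨	anatomy
骶髂关节	anatomy
心包	anatomy
心脏	anatomy
心房	anatomy
心室	anatomy
横膈	anatomy
膈肌	anatomy
膈脚	anatomy
软组织	anatomy
肌肉	anatomy
皮肤	anatomy
皮下	anatomy
腹壁	anatomy
腰大肌	anatomy
# malignancy indicators: lexical cues for malignant tumors
癌	malignancy
恶性	malignancy
瘤	malignancy
MT	malignancy
CA	malignancy
# density indicators: radiological wording correlated with size statements
高密度影	density
低密度影	density
不规则团块	density
软组织密度灶	density
软组织密度影	density
密度灶	density
密度影	density
团块影	density
肿块影	density
占位	density
结节影	density
磨玻璃影	density
# metastasis keywords
转移	metastasis
考虑转移	metastasis
多发转移	metastasis
转移可能	metastasis
转移灶	metastasis
# descriptor terms: symptom/appearance wording stripped from anatomic phrases
多发肿大	descriptor
多发	descriptor
肿大	descriptor
增大	descriptor
稍大	descriptor
小	descriptor
散在	descriptor
可疑	descriptor
轻度	descriptor
明显	descriptor
弥漫	descriptor
数枚	descriptor
几枚	descriptor
# conjunction tokens used by coordination-ellipsis completion
、	conjunction
及	conjunction
与	conjunction
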
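{
 "table1_variants.tsv": "068b62eb81a211679273bdbd79a7c9fe7a8b7d8a335c3f25f12c3ec37457bb9c",
 "table2_moat_calcium.tsv": "b94d36809c029fa3f13d2b912c3e958f6141bcbdca0c8a154f774ce0b5296942",
 "table3_cycles.csv": "ecaa0d857f5d2402618098549ec62ba5196a2903571e2eb44922db8293718a64"
}
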
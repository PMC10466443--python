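("Poverty" OR "low income" OR "no income" OR "financial difficulty" OR "financial difficulty" OR "financial difficulties" OR "financial issues" OR "financial burden" OR "financial assistance" OR "financial strain" OR "financial support" OR "financial need") NOT ("not on file", "if you qualify" OR "none" OR "doesn't qualify"~5 OR "resources")
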
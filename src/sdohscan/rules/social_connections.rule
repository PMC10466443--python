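("social isolation"~10th OR "socially isolated"~10th OR "feeling lonely"~10th OR "Loneliness" OR "isolation sad"~5) NOT ("no loneliness"~5 OR "not lonely"~5 OR "no social isolation" OR "denies loneliness"~4 OR "doesn't feel lonely" OR "isolation 14"~6 OR "can lead to loneliness and isolation" OR "isolation quarantine"~10th OR "isolation none"~5)
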
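("family stress"~5 OR "stressed" OR "stressful life"~5 OR "emotional stress" OR "headache stress"~5 OR "feels stressed"~5 OR "very stressed" OR "life stress") NOT (score OR lab OR echo OR fracture OR myocardial OR perfusion OR exercise OR ecg OR test OR myocardial OR calculate OR ischemia OR ulcer OR induce OR "stressed importance" OR "stressed good")
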
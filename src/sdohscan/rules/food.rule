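("food insecurity" OR "food insecure" OR "food pantry" OR "food stamp") NOT ("FOOD INSECURITY: Negative" OR "Denies food insecurity"~10th OR "Food insecurity - worry" OR "Food secure" OR "No food insecurity" OR "Food insecure?" OR "No concerns raised re: food insecurity" OR "does not food pantry"~10)
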
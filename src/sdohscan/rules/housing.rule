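((homeless* OR "housing instability" OR "unstable housing" OR evict* OR "shelter" OR "mold house"~10th OR "stressful home situation" OR "search for new place") OR ("home safety" AND "home environment")) NOT ("Homeless clients only" OR "volunteering homeless"~10th OR "would homeless"~5 OR "work homeless"~10th OR "homeless mother"~10th OR "homeless father"~10th OR "shelter in place" OR "shelter at home" OR "face tent" OR "oxygen tent")
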
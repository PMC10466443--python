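(unemploy* OR "job loss" OR "job fired"~10th OR "job worry"~10th OR "job ruined"~5 OR "job issues"~10th OR "problems at work" OR jobless* OR "does not get hired" OR "looking for work" OR "work fired"~10th OR "stressors work"~4 OR "out of work")
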
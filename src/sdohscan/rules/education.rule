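(Illitera* OR "lack of education" OR "poor education" OR "cannot read" OR "unable to read") NOT ("label ripped"~3 OR "glucometer" OR "eyesight" OR "vision" OR "small print")
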
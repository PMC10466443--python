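domain,code_stem
social_connections,Z60.2
social_connections,Z60.4
social_connections,Z60.8
employment,Z56.0
employment,Z56.1
employment,Z56.2
employment,Z56.89
employment,Z56.9
housing,Z59.0
housing,Z59.1
housing,Z59.8
food,Z59.4
food,Z59.41
education,Z55.0
education,Z55.1
education,Z55.2
education,Z55.3
education,Z55.4
education,Z55.8
education,Z55.9
finance,Z59.5
finance,Z59.6
finance,Z59.7
stress,Z63.7
stress,Z63.79
stress,Z73.2
stress,Z73.3
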
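ccs_code
92
121
122
123
124
125
126
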
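# Every category of every indicator is equally likely (uniform weights).
name: random
weights: {}
rules: []
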
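descriptor,hedonic_tone
fruity,2.23
sweet,2.03
sulfidic,-2.45
"sour, vinegar",-1.26
"sharp, pungent, acid",-2.34
ammonia,-2.47
fishy,-1.98
urinous,-3.34
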
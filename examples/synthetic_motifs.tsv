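name	pattern
synthetic_ccre1	TGACGT
synthetic_ccre2	TGACGC
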
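toy	120	5	60	61
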
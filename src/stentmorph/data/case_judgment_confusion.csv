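predicted,positive,negative
predicted_positive,54,15
predicted_negative,13,140
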
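predicted,real_stone,real_residual_stone
predicted_stone,78,29
predicted_residual_stone,9,70
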
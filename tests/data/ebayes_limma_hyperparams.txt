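d0=11.433597494342196 s0_sq=0.22995686600163207 df_total=15.433597494342196
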
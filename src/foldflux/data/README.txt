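Place 1L2Y.pdb here (RCSB download) to enable the Trp-cage native-contact check.
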
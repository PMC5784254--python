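# PIPK type signature table. Provisional configuration, not settled biology:
# the receptor-fused architecture defines type IV; a FYVE-like N-terminal
# accessory marks type III; types I and II are separated by the dipeptide at
# the kinase profile's activation-loop anchor position. Edit freely.
I:
  activation_anchor: KK
II:
  activation_anchor: RK
III:
  accessory_profile: FYVE
IV:
  architecture: receptor_block_preceding_PIPK
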
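# Physico-chemical residue class partition used for alignment conservation
# scoring: acidic / basic / hydrophobic / neutral / polar.
acidic	DE
basic	KRH
hydrophobic	AVLIMFWC
polar	STNQY
neutral	GP
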
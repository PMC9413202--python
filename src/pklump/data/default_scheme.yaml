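# Default lumping scheme: blood pool + lung form the lumped central
# compartment (LCEN); the non-eliminating tissues form NET; the eliminating
# organs and the portal inflow tract stay un-lumped.
lcen: [arterial, venous, lung]
net: [adipose, bone, brain, heart, muscle, skin, rest_of_body]
retained: [gut, spleen, liver, kidney]
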
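# Reference adult human (70 kg) physiology: tissue volumes (L) and regional
# blood flows (L/h).  Values follow standard compiled reference tables for a
# resting adult; cardiac output 390 L/h (6.5 L/min).  The liver flow is the
# hepatic-arterial supply only; portal inflow is the gut + spleen outflow.
# Rest-of-body is derived by closure against cardiac_output and
# total_body_volume unless given explicitly.
body_weight: 70.0
cardiac_output: 390.0
total_body_volume: 70.0
volumes:
  adipose: 13.5
  bone: 8.5
  brain: 1.45
  gut: 1.1
  heart: 0.33
  kidney: 0.31
  liver: 1.8
  lung: 0.5
  muscle: 29.0
  skin: 3.3
  spleen: 0.18
  arterial: 1.7
  venous: 3.9
flows:
  adipose: 19.5
  bone: 19.5
  brain: 46.8
  gut: 58.5
  heart: 15.6
  kidney: 74.1
  liver: 25.35
  muscle: 66.3
  skin: 19.5
  spleen: 11.7
  lung: 390.0
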
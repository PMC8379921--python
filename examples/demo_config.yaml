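# Demo: WT phenomenological agarose-pad time-lapse with an EdU pulse-chase.
preset: WT
mode: phenomenological
layout: pad
seed: 7
n_lineages: 40
duration: 380
frame_interval: 10
edu_pulse:
  pulse_start: 20
  pulse_duration: 15
  chase_duration: 180
stages: [lineage, organization, flipping, colocalization, retention]
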
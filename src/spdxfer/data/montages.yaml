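# Approximate sensorimotor channel-subset presets (10-20 / 10-10 labels).
# The published subsets for the two public motor-imagery datasets are shown
# only graphically; these lists reconstruct plausible central-area montages
# of the stated sizes (25 and 29 channels) and should be treated as
# synthetic approximations.
dataset1:
  - Fz
  - FC5
  - FC3
  - FC1
  - FCz
  - FC2
  - FC4
  - FC6
  - C5
  - C3
  - C1
  - Cz
  - C2
  - C4
  - C6
  - CP5
  - CP3
  - CP1
  - CPz
  - CP2
  - CP4
  - CP6
  - P1
  - Pz
  - P2
dataset2:
  - Fz
  - FC5
  - FC3
  - FC1
  - FCz
  - FC2
  - FC4
  - FC6
  - C5
  - C3
  - C1
  - Cz
  - C2
  - C4
  - C6
  - CP5
  - CP3
  - CP1
  - CPz
  - CP2
  - CP4
  - CP6
  - P5
  - P3
  - P1
  - Pz
  - P2
  - P4
  - P6
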
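# Default macro-region topology: names, classes, channel memberships and
# adjacency.  Residue lists are deliberately left empty; supply them from
# your own structure annotation before resolving selections.
#
# MR1-12 are entry regions on the channel mouths, MR13 is an external bridge
# between MR3 and MR12, MR14-20 are infiltration regions reachable only
# through entry regions.  MR19 (pocket) and MR20 (active-site region) are the
# infiltration termini.  MR1/4/5/6/7/8 share a common junction area.
regions:
  MR1:  {class: entry, channels: [CH2]}
  MR2:  {class: entry, channels: [CH2]}
  MR3:  {class: entry, channels: [CH2]}
  MR4:  {class: entry, channels: [CH2]}
  MR5:  {class: entry, channels: [CH3A]}
  MR6:  {class: entry, channels: [CH3B]}
  MR7:  {class: entry, channels: [CH3B]}
  MR8:  {class: entry, channels: [CH3C]}
  MR9:  {class: entry, channels: [CH3C]}
  MR10: {class: entry, channels: [CH3D]}
  MR11: {class: entry, channels: [CH3D]}
  MR12: {class: entry, channels: [CH3D]}
  MR13: {class: external, channels: []}
  MR14: {class: infiltration, channels: [CH2]}
  MR15: {class: infiltration, channels: [CH3A]}
  MR16: {class: infiltration, channels: [CH3B]}
  MR17: {class: infiltration, channels: [CH3C]}
  MR18: {class: infiltration, channels: [CH3D]}
  MR19: {class: infiltration, channels: []}
  MR20: {class: infiltration, channels: []}
adjacency:
  # CH2 funnel clique and corridor
  - [MR1, MR2]
  - [MR1, MR3]
  - [MR1, MR4]
  - [MR2, MR3]
  - [MR2, MR4]
  - [MR3, MR4]
  - [MR1, MR14]
  - [MR2, MR14]
  - [MR3, MR14]
  - [MR4, MR14]
  - [MR14, MR20]
  # common junction area
  - [MR1, MR5]
  - [MR1, MR6]
  - [MR1, MR7]
  - [MR1, MR8]
  - [MR4, MR5]
  - [MR4, MR6]
  - [MR4, MR7]
  - [MR4, MR8]
  - [MR5, MR6]
  - [MR5, MR7]
  - [MR5, MR8]
  - [MR6, MR7]
  - [MR6, MR8]
  - [MR7, MR8]
  # CH3A
  - [MR5, MR15]
  - [MR15, MR19]
  # CH3B
  - [MR6, MR16]
  - [MR7, MR16]
  - [MR16, MR19]
  # CH3C
  - [MR8, MR9]
  - [MR8, MR17]
  - [MR9, MR17]
  - [MR17, MR19]
  # CH3D (merges into CH3C; a direct pocket link is also observed)
  - [MR10, MR11]
  - [MR10, MR12]
  - [MR11, MR12]
  - [MR10, MR18]
  - [MR11, MR18]
  - [MR12, MR18]
  - [MR18, MR17]
  - [MR18, MR19]
  # external bridge
  - [MR13, MR3]
  - [MR13, MR12]
  # pocket to active-site region
  - [MR19, MR20]
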
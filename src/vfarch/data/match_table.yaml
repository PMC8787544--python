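# Full/partial matching criteria between dominant archetypes of the 16-AT
# optic-neuritis model and expert descriptive visual-field classifications.
# Keys are AT numbers (ordered by relative weight); values are descriptive
# labels parsed by vfarch.matching.parse_label.
ats:
  1:
    full: [within normal limits]
    partial: []
  2:
    full: [total loss]
    partial: [cloverleaf, three-quadrant]
  3:
    full: [superior depression]
    partial: [superior partial arcuate]
  4:
    full: [central, centrocecal, paracentral]
    partial: [enlarged blind spot]
  5:
    full: [nasal step]
    partial: [superior partial arcuate]
  6:
    full: [superior depression]
    partial: [superior partial arcuate]
  7:
    full: [superior altitudinal]
    partial: [superior arcuate, superior partial arcuate, double arcuate]
  8:
    full: [cloverleaf]
    partial: [total loss, three-quadrant]
  9:
    full: [inferior nasal quadrantanopia]
    partial: [nasal step, nasal hemianopia, inferior altitudinal, inferior arcuate,
              inferior partial arcuate]
  10:
    full: [superior temporal quadrantanopia, temporal wedge]
    partial: [temporal hemianopia, superior arcuate, superior partial arcuate]
  11:
    full: [inferior altitudinal]
    partial: [inferior arcuate, inferior partial arcuate, double arcuate]
  12:
    full: [nasal hemianopia]
    partial: [nasal step, superior nasal quadrantanopia, inferior arcuate,
              inferior partial arcuate, three-quadrant]
  13:
    full: [peripheral rim, double arcuate]
    partial: [superior arcuate, inferior arcuate]
  14:
    full: [temporal hemianopia]
    partial: [temporal wedge, superior temporal quadrantanopia,
              inferior temporal quadrantanopia, three-quadrant]
  15:
    full: [inferior temporal quadrantanopia, temporal wedge]
    partial: [temporal hemianopia, inferior partial arcuate]
  16:
    full: [nasal step]
    partial: [inferior partial arcuate, enlarged blind spot]
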
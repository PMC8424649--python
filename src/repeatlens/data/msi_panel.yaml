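# Default MSI marker panel: 6 mononucleotide, 5 dinucleotide and 5
# tetranucleotide markers plus 2 stable pentanucleotide control loci.
loci:
  - {name: NR-21, unit_bp: 1, role: marker}
  - {name: NR-24, unit_bp: 1, role: marker}
  - {name: BAT-25, unit_bp: 1, role: marker}
  - {name: BAT-26, unit_bp: 1, role: marker}
  - {name: MONO-27, unit_bp: 1, role: marker}
  - {name: NR-27, unit_bp: 1, role: marker}
  - {name: D2S123, unit_bp: 2, role: marker}
  - {name: D5S346, unit_bp: 2, role: marker}
  - {name: D17S250, unit_bp: 2, role: marker}
  - {name: D18S64, unit_bp: 2, role: marker}
  - {name: D18S69, unit_bp: 2, role: marker}
  - {name: D8S321, unit_bp: 4, role: marker}
  - {name: D20S82, unit_bp: 4, role: marker}
  - {name: D9S242, unit_bp: 4, role: marker}
  - {name: MYCL1, unit_bp: 4, role: marker}
  - {name: D20S85, unit_bp: 4, role: marker}
  - {name: Penta C, unit_bp: 5, role: control}
  - {name: Penta D, unit_bp: 5, role: control}
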
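# Protein lengths and domain intervals for the DSB break-sensor genes.
# Lengths are the human reference ORF lengths that the published
# conserved/non-conserved residue totals sum to (MRE11 708, RAD50 1312,
# NBN 754) plus CtIP/RBBP8 (897).  Domain intervals are approximate
# boundaries assembled from the structural literature on the MRN complex;
# they annotate positional histograms and lollipop exports and carry no
# statistical weight.  Versioned data, not code.
version: 1
genes:
  MRE11:
    length: 708
    domains:
      - {name: nuclease, start: 1, end: 280}
      - {name: capping, start: 281, end: 410}
      - {name: dna_binding_1, start: 411, end: 440}
      - {name: rad50_binding, start: 441, end: 500}
      - {name: gar, start: 566, end: 600}
      - {name: dna_binding_2, start: 643, end: 692}
  RAD50:
    length: 1312
    domains:
      - {name: atpase_n, start: 1, end: 200}
      - {name: coiled_coil_1, start: 201, end: 634}
      - {name: zinc_hook, start: 635, end: 734}
      - {name: coiled_coil_2, start: 735, end: 1150}
      - {name: atpase_c, start: 1151, end: 1312}
  NBN:
    length: 754
    domains:
      - {name: fha, start: 24, end: 109}
      - {name: brct1, start: 114, end: 183}
      - {name: brct2, start: 221, end: 330}
      - {name: mre11_binding, start: 682, end: 693}
      - {name: atm_binding, start: 734, end: 754}
  RBBP8:
    length: 897
    domains:
      - {name: dimerisation, start: 45, end: 160}
      - {name: mrn_interaction, start: 790, end: 897}
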
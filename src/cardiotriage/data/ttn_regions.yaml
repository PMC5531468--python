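# cardiotriage TTN sarcomeric region map, schema ttn-region-map/1.0
#
# Per-transcript 1-based inclusive residue intervals labelled with the
# sarcomeric band (Z/I/A/M). Boundaries are approximate, derived from public
# titin domain annotation for the cardiac N2B isoform (NM_003319) and the
# short novex-3 isoform (NM_133379, which terminates in the I-band and has
# no A- or M-band). The shared_all_isoforms flag marks the region shared by
# every isoform listed under isoforms_considered_all.
schema: ttn-region-map/1.0
isoforms_considered_all: [NM_003319]
transcripts:
  NM_003319:
    - {band: Z, start: 1, end: 800}
    - {band: I, start: 801, end: 14900}
    - {band: A, start: 14901, end: 24200, shared_all_isoforms: true}
    - {band: M, start: 24201, end: 26926}
  NM_133379:
    - {band: Z, start: 1, end: 450}
    - {band: I, start: 451, end: 5604}
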
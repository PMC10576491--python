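# Generic tRNA cloverleaf layouts used by the synthetic-genome generator and
# by tests.  Coordinates are tRNA-local, 1-based inclusive.  Real structure
# annotations (e.g. from a folding tool) can be supplied in the same format.
#
# "standard"  : 72-nt four-arm cloverleaf (AA 7 bp, DHU 4 bp, AC 5 bp, TPsiC
#               5 bp stems).
# "no_dhu"    : 66-nt layout lacking the dihydrouridine arm, as in the
#               mitochondrial trnS(AGY) of most birds.
standard:
  length: 72
  anticodon: [34, 36]
  arms:
    AA:
      five: [1, 7]
      three: [66, 72]
    DHU:
      five: [10, 13]
      three: [22, 25]
    AC:
      five: [27, 31]
      three: [39, 43]
    TPSIC:
      five: [49, 53]
      three: [61, 65]
no_dhu:
  length: 66
  anticodon: [25, 27]
  arms:
    AA:
      five: [1, 7]
      three: [60, 66]
    AC:
      five: [18, 22]
      three: [30, 34]
    TPSIC:
      five: [42, 46]
      three: [55, 59]
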
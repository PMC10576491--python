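# Conserved-box library for avian control-region domain scanning.
#
# provenance: study               pattern as reported for P. fuscatus CR1
#                                 (the E and C boxes contained a spurious
#                                 whitespace in the source text; stored with
#                                 the space removed)
# provenance: literature_consensus  approximate consensus drawn from the
#                                 general vertebrate/avian CR literature;
#                                 these boxes were NOT found in the
#                                 leaf-warbler CR1 and are shipped only so
#                                 that their absence is reportable.
boxes:
  - name: C-string
    pattern: CCCCCCCCCTCCCCCCCC
    max_mismatch: 1
    expected_domain: I
    provenance: study
  - name: F
    pattern: GCGCTTCTCACGAGAACCGAGCTACTCAAT
    max_mismatch: 3
    expected_domain: II
    provenance: study
  - name: E
    pattern: GTTATTGGCGTCAGGGACAT
    max_mismatch: 3
    expected_domain: II
    provenance: study
  - name: D
    pattern: CCTCCCGTGGTAACTTCAGGACCAT
    max_mismatch: 3
    expected_domain: II
    provenance: study
  - name: C
    pattern: CTGCCCTTCACTGATACTAGTGGTCGGTT
    max_mismatch: 3
    expected_domain: II
    provenance: study
  - name: bird-similarity
    pattern: CACTGATGCACTTTG
    max_mismatch: 3
    expected_domain: II
    provenance: study
  - name: B
    pattern: TCCCATTCATGGAC
    max_mismatch: 3
    expected_domain: II
    provenance: study
  - name: CSB1
    pattern: TATATAATGCAATGGTCACCGGACATG
    max_mismatch: 3
    expected_domain: III
    provenance: study
  - name: CSB2
    pattern: CAAACCCCCCCTCCCCC
    max_mismatch: 2
    expected_domain: III
    provenance: literature_consensus
  - name: CSB3
    pattern: TGCCAAACCCCAAAAACAAAGAACC
    max_mismatch: 3
    expected_domain: III
    provenance: literature_consensus
  - name: OH
    pattern: AAAGCATAACACTGAAAATG
    max_mismatch: 3
    expected_domain: III
    provenance: literature_consensus
  - name: LSP
    pattern: AAACCCCATACCCCGAACC
    max_mismatch: 3
    expected_domain: III
    provenance: literature_consensus
  - name: HSP
    pattern: AAAGCATAGCACTGAAAA
    max_mismatch: 3
    expected_domain: III
    provenance: literature_consensus
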
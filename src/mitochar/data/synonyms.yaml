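# Gene-name synonym table: common GenBank qualifier spellings -> canonical
# symbols used throughout the package.  Lookup is case-insensitive after
# stripping spaces, hyphens and underscores.  tRNA-Leu / tRNA-Ser entries that
# do not disambiguate the isoacceptor are resolved from a UUR/CUN/UCN/AGY tag
# found anywhere in the feature qualifiers; without a tag they become warnings.
synonyms:
  # protein-coding genes
  ND1: nad1
  NAD1: nad1
  NADH1: nad1
  NADHDEHYDROGENASESUBUNIT1: nad1
  ND2: nad2
  NAD2: nad2
  NADH2: nad2
  NADHDEHYDROGENASESUBUNIT2: nad2
  ND3: nad3
  NAD3: nad3
  NADH3: nad3
  NADHDEHYDROGENASESUBUNIT3: nad3
  ND4: nad4
  NAD4: nad4
  NADH4: nad4
  NADHDEHYDROGENASESUBUNIT4: nad4
  ND4L: nad4L
  NAD4L: nad4L
  NADHDEHYDROGENASESUBUNIT4L: nad4L
  ND5: nad5
  NAD5: nad5
  NADH5: nad5
  NADHDEHYDROGENASESUBUNIT5: nad5
  ND6: nad6
  NAD6: nad6
  NADH6: nad6
  NADHDEHYDROGENASESUBUNIT6: nad6
  COX1: cox1
  COXI: cox1
  COI: cox1
  CO1: cox1
  CYTOCHROMECOXIDASESUBUNITI: cox1
  CYTOCHROMECOXIDASESUBUNIT1: cox1
  COX2: cox2
  COXII: cox2
  COII: cox2
  CO2: cox2
  CYTOCHROMECOXIDASESUBUNITII: cox2
  CYTOCHROMECOXIDASESUBUNIT2: cox2
  COX3: cox3
  COXIII: cox3
  COIII: cox3
  CO3: cox3
  CYTOCHROMECOXIDASESUBUNITIII: cox3
  CYTOCHROMECOXIDASESUBUNIT3: cox3
  ATP6: atp6
  ATPASE6: atp6
  ATPSYNTHASEF0SUBUNIT6: atp6
  ATP8: atp8
  ATPASE8: atp8
  ATPSYNTHASEF0SUBUNIT8: atp8
  CYTB: cytb
  COB: cytb
  CYB: cytb
  CYTOCHROMEB: cytb
  # rRNAs
  RRNS: rrnS
  12S: rrnS
  12SRRNA: rrnS
  12SRIBOSOMALRNA: rrnS
  SRRNA: rrnS
  SSURRNA: rrnS
  SMALLSUBUNITRIBOSOMALRNA: rrnS
  RRNL: rrnL
  16S: rrnL
  16SRRNA: rrnL
  16SRIBOSOMALRNA: rrnL
  LRRNA: rrnL
  LSURRNA: rrnL
  LARGESUBUNITRIBOSOMALRNA: rrnL
  # control regions
  CR: CR
  CR1: CR1
  CR2: CR2
  DLOOP: CR
  CONTROLREGION: CR
  CONTROLREGION1: CR1
  CONTROLREGION2: CR2
  REMNANTCR2: CR2
  REMNANTCONTROLREGION: CR2
  # tRNAs, canonical and common spellings
  TRNF: trnF
  TRNAPHE: trnF
  TRNV: trnV
  TRNAVAL: trnV
  TRNI: trnI
  TRNAILE: trnI
  TRNQ: trnQ
  TRNAGLN: trnQ
  TRNM: trnM
  TRNAMET: trnM
  TRNW: trnW
  TRNATRP: trnW
  TRNA: trnA
  TRNAALA: trnA
  TRNN: trnN
  TRNAASN: trnN
  TRNC: trnC
  TRNACYS: trnC
  TRNY: trnY
  TRNATYR: trnY
  TRND: trnD
  TRNAASP: trnD
  TRNK: trnK
  TRNALYS: trnK
  TRNG: trnG
  TRNAGLY: trnG
  TRNR: trnR
  TRNAARG: trnR
  TRNH: trnH
  TRNAHIS: trnH
  TRNT: trnT
  TRNATHR: trnT
  TRNP: trnP
  TRNAPRO: trnP
  TRNE: trnE
  TRNAGLU: trnE
  "TRNL(UUR)": "trnL(UUR)"
  "TRNL(CUN)": "trnL(CUN)"
  "TRNS(UCN)": "trnS(UCN)"
  "TRNS(AGY)": "trnS(AGY)"
  "TRNALEU(UUR)": "trnL(UUR)"
  "TRNALEU(CUN)": "trnL(CUN)"
  "TRNASER(UCN)": "trnS(UCN)"
  "TRNASER(AGY)": "trnS(AGY)"
  TRNL1: "trnL(UUR)"
  TRNL2: "trnL(CUN)"
  TRNS1: "trnS(AGY)"
  TRNS2: "trnS(UCN)"
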
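# Circular mitochondrial gene-order templates, written in J-strand reading
# order starting at the trnF anchor.  Strand J = majority coding strand,
# N = minority strand (gene is read on the complement).
#
# gallus_like    : the typical avian order (single control region between
#                  trnE and trnF).
# phylloscopus   : the rearranged leaf-warbler order with a full CR1 between
#                  trnT and trnP and a degenerate remnant CR2 between trnE
#                  and trnF.
gallus_like:
  anchor: trnF
  genes:
    - [trnF, J]
    - [rrnS, J]
    - [trnV, J]
    - [rrnL, J]
    - ["trnL(UUR)", J]
    - [nad1, J]
    - [trnI, J]
    - [trnQ, N]
    - [trnM, J]
    - [nad2, J]
    - [trnW, J]
    - [trnA, N]
    - [trnN, N]
    - [trnC, N]
    - [trnY, N]
    - [cox1, J]
    - ["trnS(UCN)", N]
    - [trnD, J]
    - [cox2, J]
    - [trnK, J]
    - [atp8, J]
    - [atp6, J]
    - [cox3, J]
    - [trnG, J]
    - [nad3, J]
    - [trnR, J]
    - [nad4L, J]
    - [nad4, J]
    - [trnH, J]
    - ["trnS(AGY)", J]
    - ["trnL(CUN)", J]
    - [nad5, J]
    - [cytb, J]
    - [trnT, J]
    - [trnP, N]
    - [nad6, N]
    - [trnE, N]
    - [CR, J]
phylloscopus:
  anchor: trnF
  genes:
    - [trnF, J]
    - [rrnS, J]
    - [trnV, J]
    - [rrnL, J]
    - ["trnL(UUR)", J]
    - [nad1, J]
    - [trnI, J]
    - [trnQ, N]
    - [trnM, J]
    - [nad2, J]
    - [trnW, J]
    - [trnA, N]
    - [trnN, N]
    - [trnC, N]
    - [trnY, N]
    - [cox1, J]
    - ["trnS(UCN)", N]
    - [trnD, J]
    - [cox2, J]
    - [trnK, J]
    - [atp8, J]
    - [atp6, J]
    - [cox3, J]
    - [trnG, J]
    - [nad3, J]
    - [trnR, J]
    - [nad4L, J]
    - [nad4, J]
    - [trnH, J]
    - ["trnS(AGY)", J]
    - ["trnL(CUN)", J]
    - [nad5, J]
    - [cytb, J]
    - [trnT, J]
    - [CR1, J]
    - [trnP, N]
    - [nad6, N]
    - [trnE, N]
    - [CR2, J]
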
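# Canonical plastid gene symbols and common annotation variants.
#
# Normalization first applies mechanical rules (underscores and parentheses
# to hyphens, tRNA anticodons upper-cased, casing of the standard symbol
# restored), then this alias table for names the rules cannot fix.
aliases:
  # rps12 is trans-spliced; its 5' (exon 1) and 3' (exons 2+3) portions are
  # distinct genic regions
  rps12-5: "rps12_5'"
  rps12_5: "rps12_5'"
  rps12.5: "rps12_5'"
  rps12-3: "rps12_3'"
  rps12_3: "rps12_3'"
  rps12.3: "rps12_3'"
  # legacy/alternative symbols seen in deposited plastomes
  ycf1a: ycf1
  ycf1b: ycf1
  orf42: ycf15
  orf56: ycf15
  lhbA: psbZ
  # 4.5S/5S rRNA naming variants
  rrn4.5S: rrn4.5
  rrn5S: rrn5
  rrn16S: rrn16
  rrn23S: rrn23
# Standard symbols used to restore canonical casing (matched
# case-insensitively on the gene body).
canonical:
  - accD
  - atpA
  - atpB
  - atpE
  - atpF
  - atpH
  - atpI
  - ccsA
  - cemA
  - clpP
  - infA
  - matK
  - ndhA
  - ndhB
  - ndhC
  - ndhD
  - ndhE
  - ndhF
  - ndhG
  - ndhH
  - ndhI
  - ndhJ
  - ndhK
  - petA
  - petB
  - petD
  - petG
  - petL
  - petN
  - psaA
  - psaB
  - psaC
  - psaI
  - psaJ
  - psbA
  - psbB
  - psbC
  - psbD
  - psbE
  - psbF
  - psbH
  - psbI
  - psbJ
  - psbK
  - psbL
  - psbM
  - psbN
  - psbT
  - psbZ
  - rbcL
  - rpl2
  - rpl14
  - rpl16
  - rpl20
  - rpl22
  - rpl23
  - rpl32
  - rpl33
  - rpl36
  - rpoA
  - rpoB
  - rpoC1
  - rpoC2
  - rps2
  - rps3
  - rps4
  - rps7
  - rps8
  - rps11
  - rps14
  - rps15
  - rps16
  - rps18
  - rps19
  - rrn4.5
  - rrn5
  - rrn16
  - rrn23
  - ycf1
  - ycf2
  - ycf3
  - ycf4
  - ycf15
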
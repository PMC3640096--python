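# Ordered IR/SC boundary typing rules; first match wins.
#
# Each rule constrains up to three junction contexts, identified by their
# anchor side rather than by J-labels (published J nomenclature is used
# inconsistently across junction descriptions):
#   rps19_context : junction at the LSC-IR boundary near rps19/rpl2
#   ndhf_context  : IR-SSC-side junction nearer ndhF/trnN-GUU
#   ycf1_context  : SSC-IR-side junction nearer ycf1
# Context values: "gene" (inside the side's anchor gene), "spacer"
# (intergenic), "other" (inside a non-anchor gene, i.e. the IR has moved
# past the anchor), or an explicit feature name.
#
# Type I is the common euasterid organization (ycf1 spanning the SSC-IR
# boundary); its four subtypes form the 2x2 grid over whether the LSC-IR
# junction falls in rps19 or the rps19-rpl2 spacer, and whether the
# IR-SSC-side junction falls in ndhF or the trnN-ndhF spacer. Types II-V
# are coarse expansion/contraction defaults and are meant to be edited;
# large-rearrangement types (VI, VII) require synteny evidence that a
# junction profile alone cannot supply and are not encoded here.
rules:
  - label: I-2
    rps19_context: gene
    ndhf_context: spacer
    ycf1_context: gene
    note: most common euasterid arrangement
  - label: I-1
    rps19_context: spacer
    ndhf_context: spacer
    ycf1_context: gene
  - label: I-4
    rps19_context: gene
    ndhf_context: gene
    ycf1_context: gene
  - label: I-3
    rps19_context: spacer
    ndhf_context: gene
    ycf1_context: gene
  - label: II
    rps19_context: other
    ycf1_context: gene
    note: IR expansion beyond the LSC-side anchor genes
  - label: III
    rps19_context: other
    ndhf_context: other
    note: IR contraction at the LSC side with SSC-side expansion
  - label: V
    rps19_context: spacer
    ndhf_context: spacer
    ycf1_context: spacer
    note: IR contracted clear of all anchor genes
  - label: I
    ycf1_context: gene
    note: Type I with an atypical LSC-side context
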
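# Default family/class rules for the human E3 ligase census.
#
# Families match when any listed domain, motif, or interaction-partner claim
# is present in a gene's evidence. Curator-only families (empty claim sets)
# are entered solely through family-context curator votes.
RING:
  domains: [RING]
  motifs: []
  partners: []
dRING:
  domains: [U-box, SP-RING, hemiRING, RING-like]
  motifs: []
  partners: []
HECT:
  domains: [HECT]
  motifs: []
  partners: []
RBR:
  domains: [RING1, IBR, RING2]
  motifs: []
  partners: []
CRL1_SR:
  domains: [F-box]
  motifs: []
  partners: [CUL1, SKP1]
CRL2_SR:
  domains: []
  motifs: [BC-box-CUL2-box]
  partners: [CUL2, ELOB, ELOC]
CRL3_SR:
  domains: [BTB]
  motifs: [3-box]
  partners: [CUL3]
CRL4_SR:
  domains: []
  motifs: [helix-loop-helix]
  partners: [DDB1]
CRL5_SR:
  domains: [SOCS-box]
  motifs: []
  partners: [CUL5, ELOB, ELOC]
APCC_SR:
  domains: []
  motifs: []
  partners: []
atypical:
  domains: []
  motifs: []
  partners: []
pseudo:
  domains: []
  motifs: []
  partners: []
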
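# Direction metadata for the 44 analysed dbNSFP-style predictor columns.
# direction +1: higher score = more deleterious; -1: lower = more deleterious.
# Columns on the exclude list are dropped from input matrices with a notice.
predictors:
  SIFT: {direction: -1}
  SIFT4G: {direction: -1}
  Polyphen2_HDIV: {direction: 1}
  Polyphen2_HVAR: {direction: 1}
  LRT: {direction: -1}
  MutationTaster: {direction: 1}
  MutationAssessor: {direction: 1}
  FATHMM: {direction: -1}
  PROVEAN: {direction: -1}
  VEST4: {direction: 1}
  MetaSVM: {direction: 1}
  MetaLR: {direction: 1}
  MetaRNN: {direction: 1}
  M-CAP: {direction: 1}
  REVEL: {direction: 1}
  MutPred: {direction: 1}
  MVP: {direction: 1}
  MPC: {direction: 1}
  PrimateAI: {direction: 1}
  DEOGEN2: {direction: 1}
  BayesDel_addAF: {direction: 1}
  BayesDel_noAF: {direction: 1}
  ClinPred: {direction: 1}
  LIST-S2: {direction: 1}
  VARITY_R: {direction: 1}
  VARITY_ER: {direction: 1}
  CADD: {direction: 1}
  DANN: {direction: 1}
  fathmm-MKL_coding: {direction: 1}
  fathmm-XF_coding: {direction: 1}
  Eigen-raw_coding: {direction: 1}
  Eigen-PC-raw_coding: {direction: 1}
  GenoCanyon: {direction: 1}
  integrated_fitCons: {direction: 1}
  GM12878_fitCons: {direction: 1}
  H1-hESC_fitCons: {direction: 1}
  HUVEC_fitCons: {direction: 1}
  GERP++_RS: {direction: 1}
  phyloP100way_vertebrate: {direction: 1}
  phyloP30way_mammalian: {direction: 1}
  phyloP17way_primate: {direction: 1}
  phastCons100way_vertebrate: {direction: 1}
  phastCons30way_mammalian: {direction: 1}
  phastCons17way_primate: {direction: 1}
exclude:
  - LINSIGHT
  - CADD_v1.9
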
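variant	splice_donor_loss	ddg_stability
V1	NA	0.32
V2	NA	-1.22
V32	0.90	NA
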
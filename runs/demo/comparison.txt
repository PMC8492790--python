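method   EEGNet_0  EEGNet_1  EEGNet_2   lda    svm
subject                                           
S03         66.67     98.33    100.00 96.67 100.00
Mean        66.67     98.33    100.00 96.67 100.00
paired test: wilcoxon; reference: EEGNet_2
  EEGNet_2 vs EEGNet_0: p = 1
  EEGNet_2 vs EEGNet_1: p = 1
  EEGNet_2 vs lda: p = 1
  EEGNet_2 vs svm: p = 1
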
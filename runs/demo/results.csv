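subject,method,split_seed,accuracy
S03,EEGNet_0,1077619458,0.75
S03,EEGNet_0,1077619459,0.6
S03,EEGNet_0,1077619460,0.65
S03,EEGNet_1,1077619458,1.0
S03,EEGNet_1,1077619459,1.0
S03,EEGNet_1,1077619460,0.95
S03,EEGNet_2,1077619458,1.0
S03,EEGNet_2,1077619459,1.0
S03,EEGNet_2,1077619460,1.0
S03,svm,1077619458,1.0
S03,svm,1077619459,1.0
S03,svm,1077619460,1.0
S03,lda,1077619458,0.95
S03,lda,1077619459,0.95
S03,lda,1077619460,1.0
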
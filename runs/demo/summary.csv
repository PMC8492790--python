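subject,EEGNet_0,EEGNet_1,EEGNet_2,lda,svm
S03,66.66666666666666,98.33333333333334,100.0,96.66666666666667,100.0
Mean,66.66666666666666,98.33333333333334,100.0,96.66666666666667,100.0
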
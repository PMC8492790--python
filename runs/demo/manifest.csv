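subject_id,role,cohort,seed,erd_depth,snr_db
S01,source,easy,1041414679,0.6172663818082036,5.3256537222663285
S02,source,easy,919520227,0.6247547845428862,6.615108264093747
S03,target,hard,1759483941,0.32882261448778577,0.4035208263871186
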
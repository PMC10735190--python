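subject_id,X
Subject01,9.7
Subject02,29.35
Subject03,12.88
Subject04,31
Subject05,8.6
Subject06,20.71
Subject07,4.35
Subject08,13.38
Subject09,18.24
Subject10,7
Subject11,1
Subject12,26
Subject13,26.36
Subject14,34
Subject15,9
Subject16,22.18
Subject17,11.59
Subject18,28.7
Subject19,20
Subject20,7.06
Subject21,15.41
Subject22,1
Subject23,4.47
Subject24,27.47
Subject25,14.76
Subject26,30.53
Subject27,13.59
Subject28,34.59
Subject29,27
Subject30,16.59
Subject31,10
Subject32,19.88
Subject33,13
Subject34,21.47
Subject35,31
Subject36,12.18
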
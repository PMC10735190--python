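subject_id,X,pred_rest,pred_task
Subject01,9.7,class_1,class_2
Subject02,29.35,class_1,class_2
Subject03,12.88,class_1,class_1
Subject04,31,class_1,class_2
Subject05,8.6,class_1,class_2
Subject06,20.71,class_1,class_2
Subject07,4.35,class_1,class_2
Subject08,13.38,class_2,class_2
Subject09,18.24,class_1,class_2
Subject10,7,class_1,class_2
Subject11,1,class_2,class_1
Subject12,26,class_2,class_2
Subject13,26.36,class_1,class_1
Subject14,34,class_2,class_2
Subject15,9,class_2,class_2
Subject16,22.18,class_1,class_1
Subject17,11.59,class_2,class_2
Subject18,28.7,class_2,class_2
Subject19,20,class_2,class_2
Subject20,7.06,class_1,class_2
Subject21,15.41,class_2,class_2
Subject22,1,class_1,class_2
Subject23,4.47,class_1,class_2
Subject24,27.47,class_2,class_2
Subject25,14.76,class_2,class_2
Subject26,30.53,class_1,class_1
Subject27,13.59,class_2,class_2
Subject28,34.59,class_1,class_2
Subject29,27,class_1,class_2
Subject30,16.59,class_1,class_1
Subject31,10,class_2,class_2
Subject32,19.88,class_2,class_2
Subject33,13,class_1,class_2
Subject34,21.47,class_2,class_2
Subject35,31,class_1,class_1
Subject36,12.18,class_1,class_2
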
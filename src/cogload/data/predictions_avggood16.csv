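subject_id,X,pred_rest,pred_task
Subject32,29.35,class_2,class_2
Subject19,12.88,class_1,class_2
Subject06,31,class_2,class_2
Subject34,20.71,class_2,class_1
Subject16,13.38,class_2,class_1
Subject12,18.24,class_2,class_2
Subject13,26,class_2,class_2
Subject29,26.36,class_2,class_2
Subject24,27.47,class_1,class_1
Subject18,28.7,class_1,class_2
Subject02,29.35,class_1,class_2
Subject26,30.53,class_2,class_1
Subject04,31,class_2,class_2
Subject35,31,class_1,class_2
Subject14,34,class_2,class_2
Subject28,34.59,class_2,class_2
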
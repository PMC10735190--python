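subject_id,X,pred_rest,pred_task
Subject01,9.7,class_1,class_2
Subject05,8.6,class_1,class_2
Subject07,4.35,class_1,class_2
Subject10,7,class_1,class_2
Subject11,1,class_2,class_1
Subject15,9,class_2,class_2
Subject20,7.06,class_1,class_2
Subject22,1,class_1,class_2
Subject23,4.47,class_1,class_2
Subject31,10,class_2,class_2
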
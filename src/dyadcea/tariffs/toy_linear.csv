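form,term,level,coefficient
additive_decrement,intercept,,1.0
additive_decrement,mobility,2,0.1
additive_decrement,mobility,3,0.2
additive_decrement,self_care,2,0.1
additive_decrement,self_care,3,0.2
additive_decrement,usual_activities,2,0.1
additive_decrement,usual_activities,3,0.2
additive_decrement,pain_discomfort,2,0.1
additive_decrement,pain_discomfort,3,0.2
additive_decrement,anxiety_depression,2,0.1
additive_decrement,anxiety_depression,3,0.2
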
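# SYNTHETIC stand-in for a Swedish experience-based EQ-5D-3L value set.
# Coefficients are fabricated with realistic structure and range (high
# intercept, mild decrements, floor well above 0); replace this file with
# the licensed published value set before any real-data analysis.
form,term,level,coefficient
additive_decrement,intercept,,0.969
additive_decrement,mobility,2,0.065
additive_decrement,mobility,3,0.165
additive_decrement,self_care,2,0.030
additive_decrement,self_care,3,0.090
additive_decrement,usual_activities,2,0.045
additive_decrement,usual_activities,3,0.095
additive_decrement,pain_discomfort,2,0.060
additive_decrement,pain_discomfort,3,0.165
additive_decrement,anxiety_depression,2,0.065
additive_decrement,anxiety_depression,3,0.185
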
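# SYNTHETIC stand-in for a Spanish time-trade-off EQ-5D-3L value set.
# Fabricated coefficients with realistic structure and range (states worse
# than dead possible); replace with the licensed published value set before
# any real-data analysis.
form,term,level,coefficient
additive_decrement,intercept,,1.0
additive_decrement,mobility,2,0.106
additive_decrement,mobility,3,0.430
additive_decrement,self_care,2,0.130
additive_decrement,self_care,3,0.380
additive_decrement,usual_activities,2,0.070
additive_decrement,usual_activities,3,0.260
additive_decrement,pain_discomfort,2,0.090
additive_decrement,pain_discomfort,3,0.320
additive_decrement,anxiety_depression,2,0.080
additive_decrement,anxiety_depression,3,0.270
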
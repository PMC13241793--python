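# SYNTHETIC stand-in for a European EQ-5D VAS value set. Fabricated
# coefficients with realistic structure and range; replace with the
# licensed published value set before any real-data analysis.
form,term,level,coefficient
additive_decrement,intercept,,0.98
additive_decrement,mobility,2,0.080
additive_decrement,mobility,3,0.210
additive_decrement,self_care,2,0.055
additive_decrement,self_care,3,0.150
additive_decrement,usual_activities,2,0.065
additive_decrement,usual_activities,3,0.160
additive_decrement,pain_discomfort,2,0.095
additive_decrement,pain_discomfort,3,0.240
additive_decrement,anxiety_depression,2,0.070
additive_decrement,anxiety_depression,3,0.180
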
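condition,burden_score,cost_score,innovation_score,overall_gap
Diabetes mellitus,0.46,0.77,0.77,0.61
Osteoarthritis,0.47,0.41,0.27,0.46
Drug use disorders,0.48,0.26,0.22,0.39
Ischemic heart disease,0.48,0.24,0.26,0.38
Alzheimer disease and other dementias,0.19,0.38,0.29,0.37
Chronic kidney disease,0.32,0.27,0.05,0.36
Chronic obstructive pulmonary disease,0.30,0.22,0.09,0.33
Cirrhosis and other liver disease,0.26,0.22,0.10,0.31
Colorectal cancer,0.23,0.22,0.14,0.30
Stroke,0.27,0.22,0.35,0.30
Depressive disorders,0.22,0.25,0.29,0.30
"Tracheal, bronchus, and lung cancer",0.24,0.24,0.37,0.29
Lower respiratory infections,0.16,0.18,0.18,0.27
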
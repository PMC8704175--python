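group,patient,dsc,hd95_mm
clinician_scoring,1,0.91,9.51
clinician_scoring,2,0.89,8.13
clinician_scoring,3,0.89,9.02
clinician_scoring,4,0.93,5.94
clinician_scoring,5,0.93,7.05
clinician_scoring,6,0.93,5.97
clinician_scoring,7,0.88,11.68
clinician_scoring,8,0.89,10.46
clinician_scoring,9,0.93,7.60
clinician_scoring,10,0.90,10.50
turing_test,11,0.88,9.62
turing_test,12,0.84,10.08
turing_test,13,0.89,8.46
turing_test,14,0.88,9.79
turing_test,15,0.92,5.02
turing_test,16,0.91,5.47
turing_test,17,0.89,8.11
turing_test,18,0.90,6.98
turing_test,19,0.90,7.09
turing_test,20,0.91,5.76
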
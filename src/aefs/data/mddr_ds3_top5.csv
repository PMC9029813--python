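activity_class,TAN,SQB,AE1_DR,AE2_DR,AE3_DR
09249,24.17,17.8,26.08,26.02,25.79
12455,10.29,11.42,14.85,15.86,14.99
12464,15.22,16.79,19.76,20.74,19.78
31281,29.62,29.05,32.33,33.19,35.01
43210,16.07,14.12,19.11,20.22,19.55
71522,12.37,13.82,15.44,15.07,16.06
75721,25.21,30.61,33.71,34.45,35.33
78331,15.01,11.97,13.22,13.10,14.12
78348,24.67,21.14,20.87,20.98,21.89
78351,11.71,13.30,17.50,16.45,18.08
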
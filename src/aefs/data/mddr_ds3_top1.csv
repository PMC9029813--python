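activity_class,TAN,SQB,AE1_DR,AE2_DR,AE3_DR
09249,12.12,10.99,15.01,16.03,17.76
12455,6.57,7.03,7.88,9.17,6.77
12464,8.17,6.92,11.12,12.50,12.04
31281,16.95,18.67,17.66,17.75,16.5
43210,6.27,6.83,9.76,9.07,10.90
71522,3.75,6.57,7.19,9.14,9.02
75721,17.32,20.38,22.29,21.66,23.90
78331,6.31,6.16,6.09,5.06,8.98
78348,10.15,8.99,9.11,6.89,6.40
78351,9.84,12.5,14.02,15.78,16.06
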
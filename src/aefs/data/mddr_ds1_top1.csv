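activity_class,TAN,ASMTP,SQB,AE1_DR,AE2_DR,AE3_DR
31420,69.69,73.84,73.73,71.31,70.43,70.99
71523,25.94,15.03,26.84,28.37,25.37,25.85
37110,9.63,20.82,24.73,21.40,21.90,20.92
31432,35.82,37.14,36.66,41.34,40.71,41.04
42731,17.77,19.53,21.17,19.23,17.67,22.03
06233,13.87,10.35,12.49,13.01,14.04,14.87
06245,6.51,5.50,6.03,6.03,7.78,7.08
07701,8.63,7.99,11.35,9.87,8.91,12.31
06235,9.71,9.94,10.15,10.71,11.07,10.49
78374,13.69,13.90,13.08,11.91,12.04,13.74
78331,7.17,6.89,5.92,7.23,7.07,8.14
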
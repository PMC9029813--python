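activity_class,TAN,ASMTP,SQB,AE1_DR,AE2_DR,AE3_DR
31420,83.49,86,87.75,85.8,85.03,87.08
71523,48.92,51.33,60.16,55.21,57.22,56.41
37110,21.01,23.87,39.81,43.53,42.17,41.79
31432,74.29,76.63,82,78.72,80.40,80.12
42731,29.68,32.9,28.77,27.04,26.03,27.04
06233,27.68,26.2,20.96,23.8,24.11,25.19
06245,16.54,15.5,15.39,19.76,21.17,21.07
07701,24.09,23.9,26.90,25.21,24.78,26.25
06235,20.06,23.6,22.47,22.08,21.91,24.17
78374,20.51,22.26,20.95,18.19,19.88,23.74
78331,16.2,15,10.31,11.07,11.9,13.19
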
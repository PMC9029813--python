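activity_class,TAN,ASMTP,SQB,AE1_DR,AE2_DR,AE3_DR
07707,70.39,76.17,74.22,73.33,77.78,80.24
07708,56.58,99.99,100,97.9,98.03,99.28
31420,88.19,95.75,95.24,92.08,94.11,95.22
42710,88.09,96.73,93,91.06,91.27,92.71
64100,93.75,98.27,98.94,98.90,97.41,97.85
64200,77.68,96.16,98.93,93.80,94.80,95.90
64220,52.19,94.13,90.9,91.5,92.09,92.33
64500,44.8,90.6,92.72,89.04,91.08,91.07
64350,91.71,98.6,93.75,91.11,92.44,90.9
75755,94.82,97.27,98.75,98.08,97.09,97.19
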
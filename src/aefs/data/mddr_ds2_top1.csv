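activity_class,TAN,ASMTP,SQB,AE1_DR,AE2_DR,AE3_DR
07707,61.84,67.86,72.09,70.15,73.18,73.46
07708,47.03,97.87,95.68,95.73,97.57,98.75
31420,65.10,73.51,78.56,73.75,75.17,74.04
42710,81.27,81.17,76.82,80.12,83.03,82.01
64100,80.31,86.62,87.80,86.19,88.17,87.79
64200,53.84,69.11,70.18,67.61,67.02,69.08
64220,38.64,66.26,67.58,67.96,66.74,67.19
64500,30.56,46.24,79.20,74.04,76.02,79.72
64350,80.18,68.01,81.68,81.96,81.77,83.09
75755,87.56,93.48,98.02,97.26,97.08,98.15
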
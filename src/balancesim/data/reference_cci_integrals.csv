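delay_ms,pair,0,2,4,6,8,10,20,40,60,80
100,VAS-HM,2.34,4.33,5.96,5.65,6.17,7.10,7.49,6.34,5.42,7.90
100,RF-HM,1.60,1.49,1.47,1.33,1.33,1.33,2.82,3.34,6.73,2.38
100,IL-HM,1.60,1.49,1.43,1.38,1.37,1.54,3.42,5.58,12.35,7.60
100,TA-GAS,2.00,1.67,1.69,1.62,1.42,1.74,1.51,1.63,1.33,4.88
100,TA-SOL,1.20,1.22,1.23,1.31,1.48,1.25,3.41,4.89,5.60,4.30
150,VAS-HM,2.76,4.10,4.02,3.88,3.34,6.06,6.59,5.83,8.29,8.36
150,RF-HM,1.61,1.41,2.21,4.68,2.97,3.58,2.91,7.21,8.37,3.19
150,IL-HM,1.61,1.39,1.42,2.01,2.39,4.34,4.38,3.47,6.42,7.30
150,TA-GAS,1.79,1.46,1.60,1.75,1.67,1.71,1.62,2.14,1.60,3.50
150,TA-SOL,1.18,1.17,1.23,1.17,1.25,1.83,3.54,6.11,4.26,5.37
200,VAS-HM,5.57,5.39,6.97,7.98,8.78,5.83,5.84,6.25,11.36,12.83
200,RF-HM,3.02,4.07,4.68,6.75,6.73,2.87,2.88,4.67,7.94,16.79
200,IL-HM,1.33,3.88,4.29,6.22,4.73,3.44,4.47,7.10,14.51,15.64
200,TA-GAS,1.67,1.64,1.57,1.87,1.76,1.56,1.56,1.31,1.83,4.75
200,TA-SOL,1.18,1.60,1.23,1.15,1.69,2.46,2.00,4.36,5.86,8.91
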
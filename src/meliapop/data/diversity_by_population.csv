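population,na,na_sd,ne,ne_sd,he,he_sd,h,h_sd,i,i_sd,pic
412,8.07,2.71,5.24,1.64,0.82,0.07,0.79,0.07,1.78,0.34,0.761
741,7.53,2.56,5.33,1.84,0.82,0.07,0.79,0.07,1.75,0.36,0.759
631,6.40,2.41,4.61,1.90,0.77,0.12,0.74,0.11,1.57,0.44,0.698
739,8.00,2.62,5.70,2.29,0.82,0.09,0.79,0.09,1.80,0.41,0.763
205,7.20,2.51,5.06,1.77,0.81,0.07,0.78,0.07,1.71,0.33,0.749
524,6.60,2.56,4.56,1.73,0.78,0.10,0.75,0.09,1.58,0.40,0.709
525,6.00,2.93,4.09,1.86,0.74,0.11,0.72,0.10,1.46,0.43,0.666
628,7.60,2.72,5.29,1.99,0.81,0.08,0.78,0.08,1.74,0.38,0.752
415,6.87,2.36,4.58,1.56,0.78,0.09,0.76,0.09,1.62,0.37,0.718
307,7.20,2.39,5.30,2.05,0.81,0.10,0.78,0.10,1.72,0.41,0.746
842,6.53,2.83,4.56,2.09,0.77,0.11,0.74,0.10,1.56,0.45,0.696
308,7.87,2.47,5.36,1.33,0.83,0.06,0.80,0.06,1.80,0.29,0.773
310,7.80,2.14,5.33,1.81,0.82,0.07,0.79,0.06,1.78,0.31,0.764
843,8.60,3.44,5.78,2.62,0.82,0.09,0.79,0.09,1.81,0.46,0.760
102,6.93,2.21,4.83,1.42,0.80,0.08,0.77,0.08,1.67,0.33,0.738
844,7.87,2.64,5.55,2.18,0.82,0.08,0.79,0.08,1.79,0.38,0.764
1061,8.07,2.79,5.51,2.28,0.81,0.10,0.78,0.10,1.78,0.44,0.751
1767,6.87,2.17,5.05,1.71,0.81,0.08,0.78,0.08,1.69,0.35,0.746
754,6.73,2.99,4.76,2.38,0.77,0.11,0.75,0.10,1.59,0.46,0.704
959,6.60,2.29,4.78,1.95,0.79,0.09,0.76,0.09,1.62,0.36,0.723
1565,7.20,1.70,4.94,1.40,0.81,0.06,0.78,0.06,1.71,0.27,0.750
1666,7.60,2.41,5.18,1.61,0.81,0.08,0.79,0.08,1.75,0.34,0.754
1768,7.60,2.10,5.29,1.76,0.82,0.08,0.79,0.07,1.76,0.33,0.759
1464,7.40,2.61,5.10,1.83,0.81,0.06,0.78,0.06,1.72,0.33,0.752
1363,7.33,2.49,5.14,1.86,0.81,0.10,0.78,0.09,1.71,0.40,0.742
652,7.60,1.76,5.32,1.87,0.82,0.06,0.79,0.06,1.76,0.29,0.763
1869,7.13,2.50,4.71,1.70,0.79,0.08,0.76,0.08,1.64,0.36,0.725
1060,7.27,2.66,4.99,2.25,0.79,0.10,0.76,0.10,1.67,0.43,0.724
1162,7.60,2.06,5.19,1.58,0.82,0.05,0.79,0.05,1.76,0.27,0.764
858,6.73,2.87,4.71,2.16,0.77,0.11,0.74,0.11,1.59,0.45,0.703
248,6.67,1.50,4.58,1.07,0.80,0.06,0.77,0.06,1.63,0.24,0.734
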
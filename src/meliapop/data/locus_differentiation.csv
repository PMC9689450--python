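locus,gst,a,b,p,r
SSR02,0.0731,0.0721,-0.0023,0.300,0.0400
SSR29,0.0915,0.0580,-0.0003,0.520,0.0032
SSR54,0.1010,-0.2353,0.0221,0.010,0.2625
SSR59,0.0687,0.0856,-0.0035,0.240,0.0640
SSR74,0.1230,-0.1200,0.0145,0.030,0.1552
SSR111,0.0623,-0.1486,0.0138,0.010,0.2311
SSR113,0.1017,0.0060,0.0042,0.260,0.0374
SSR114,0.1064,0.0920,-0.0021,0.330,0.0224
SSR116,0.1097,-0.0553,0.0091,0.060,0.1100
SSR117,0.1281,-0.1173,0.0147,0.050,0.1265
SSR118,0.0762,0.0537,-0.0008,0.460,0.0141
SSR119,0.0448,0.0125,0.0009,0.350,0.0283
SSR120,0.0327,0.0065,0.0008,0.280,0.0332
SSR122,0.0866,-0.0019,0.0039,0.190,0.0608
SSR123,0.0984,-0.2884,0.0260,0.010,0.3056
Multilocus,0.0860,-0.0353,0.0063,0.010,0.2449
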
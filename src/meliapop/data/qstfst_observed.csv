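trait_code,qst_minus_fst,crit_lo,crit_hi,stars
HEIT1,-0.0615,-0.0529,0.0720,*
HEIT2,-0.0648,-0.0565,0.0833,*
HEIT3,-0.0711,-0.0565,0.0815,**
HEIT4,-0.0484,-0.0578,0.0885,ns
HEIT5,-0.0330,-0.0597,0.0917,ns
GBH1,0.0306,-0.0540,0.0713,ns
DBH2,-0.0127,-0.0567,0.0813,ns
DBH3,-0.0120,-0.0558,0.0773,ns
DBH4,-0.0072,-0.0566,0.0803,ns
DBH5,-0.0285,-0.0557,0.0792,ns
NOB1,-0.0112,-0.0533,0.0699,ns
NOB2,-0.0112,-0.0533,0.0699,ns
CBH3,-0.0120,-0.0558,0.0773,ns
CBH4,0.0329,-0.0817,0.3663,ns
CBH5,0.0789,-0.0859,0.4238,ns
SMT1,-0.0156,-0.0593,0.0984,ns
SMT2,-0.0591,-0.0609,0.0999,ns
SMT3,-0.0725,-0.0584,0.0937,**
SMT4,-0.0639,-0.0647,0.1297,ns
SMT5,-0.0477,-0.0613,0.1001,ns
CRB1,-0.0179,-0.0540,0.0753,ns
CRB2,0.0041,-0.0586,0.0929,ns
CRB3,-0.0081,-0.0574,0.0925,ns
CRB4,-0.0099,-0.0571,0.0873,ns
CRB5,-0.0245,-0.0573,0.0866,ns
SR1,0.0350,-0.0569,0.0825,ns
SR2,0.1047,-0.0557,0.0790,*
SR3,0.1016,-0.0551,0.0763,*
SR4,0.1254,-0.0558,0.0756,**
SR5,0.1235,-0.0536,0.0746,**
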
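code,name,acid_class,s_mg_ml,sa_exp,pka1,pka2,dg_r,pk_r_printed,p_ma_printed,log_beta_printed,c0,solubility_limit
M,Meloxicam,api,0.17,,4.18,,2.45,1.73,,,0.1,
1,1-Hydroxy-2-naphthoic acid,mono,0.34,0.31,2.70,,-6.43,-4.53,1.05,-5.58,0.5,0.1
2,Salicylic acid,mono,0.26,0.18,2.97,,-6.96,-4.91,-0.30,-4.61,0.5,
3,Succinic acid,di,0.21,0.09,4.20,5.60,-6.13,-4.32,-5.30,-3.33,0.5,
4,4-Hydroxybenzoic acid,mono,0.16,-0.02,4.54,,-6.34,-4.47,-1.42,-3.04,0.5,
5,Glutaric acid,di,0.13,-0.10,4.30,5.40,-4.59,-3.23,-3.22,-3.25,0.5,
6,Maleic acid,di,0.23,0.13,1.91,6.33,-9.72,-6.85,-8.25,-5.44,0.5,
7,l-Malic acid,di,0.14,-0.08,3.46,5.10,-5.45,-3.84,-3.58,-4.10,0.5,
8,Benzoic acid,mono,0.15,-0.04,4.20,,-6.42,-4.52,-1.14,-3.38,0.5,
10,Hydrocinnamic acid,mono,0.16,-0.03,4.57,,-5.69,-4.01,-1.00,-3.01,0.5,
11,Glycolic acid,mono,0.16,-0.02,3.60,,-7.84,-5.53,-1.55,-3.98,0.5,
12,Fumaric Acid,di,0.18,0.02,3.30,4.44,-7.09,-5.00,-5.72,-4.27,0.5,
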
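model,auc,f1,acc,pre,sen,spe
DT,0.698,0.426,0.674,0.336,0.585,0.698
RF,0.697,0.447,0.667,0.344,0.646,0.675
XGB,0.718,0.456,0.654,0.339,0.701,0.642
LGBM,0.710,0.455,0.632,0.330,0.735,0.605
SVM,0.698,0.296,0.767,0.402,0.236,0.907
NB,0.705,0.456,0.645,0.336,0.714,0.627
GBDT,0.725,0.453,0.687,0.355,0.623,0.703
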
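name,group,cLogD7.4,cLogP,abraham_acidity,abraham_basicity,hbd,hba,hb_total,rotatable_bonds,abraham_volume,abraham_polarizability,psa,mw,abraham_mri
Acrivastine,A,2.03,4.55,0.59,1.50,1,4,5,6,2.81,2.07,53,348,2.10
Digoxin,A,0.90,0.90,1.72,4.62,6,14,20,13,5.75,5.34,203,780,3.20
Erythromycin,A,1.20,1.90,1.02,4.71,5,14,19,12,5.77,3.55,194,733,1.97
GSK1,A,3.07,3.75,1.08,2.67,10,3,13,7,3.83,5.28,130,571,3.83
Mitoxantrone,A,1.00,1.55,0.52,2.88,8,10,18,16,3.29,2.06,163,444,3.31
Monensin,A,0.96,4.01,1.49,3.55,4,11,15,13,5.24,2.44,153,670,1.61
Puromycin,A,0.97,1.30,0.51,3.56,5,12,17,11,3.42,3.58,164,471,3.38
Saquinavir,A,3.60,4.03,1.61,4.68,6,11,17,14,5.89,6.30,167,670,4.25
Chloroquine,B,1.59,4.41,0.20,1.59,1,3,4,8,2.63,1.73,28,319,1.91
Colchicine,B,1.07,1.07,0.37,1.96,1,7,8,5,2.99,2.96,87,399,2.11
Domperidone,B,2.93,4.05,0.65,2.23,2,7,9,5,3.06,3.09,79,425,3.81
Eletriptan,B,0.23,2.98,0.003,1.84,1,4,5,6,2.93,3.17,53,382,2.74
GSK2,B,2.64,3.28,0.83,2.56,7,2,9,6,3.76,3.78,100,495,3.76
GSK3,B,3.89,3.11,0.003,0.80,3,0,3,9,3.88,2.36,33,466,3.88
Indacaterol,B,2.42,-1.71,0.54,2.06,5,1,6,4,3.09,2.54,59,393,3.09
Rh-123,B,4.01,4.01,0.50,1.21,4,5,9,5,2.56,2.90,90,344,3.27
Salbutamol,B,-1.44,0.70,1.08,1.91,4,4,8,8,1.98,1.41,73,239,1.41
Salmeterol,B,1.15,3.07,1.08,2.11,4,5,9,19,3.49,2.11,82,416,2.07
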
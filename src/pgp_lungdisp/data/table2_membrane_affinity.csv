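name,group,logk_iam,mlv_partitioning
Acrivastine,A,1.50,0.96
Digoxin,A,0.92,0.30
Erythromycin,A,0.88,0.46
GSK1,A,1.08,0.65
Mitoxantrone,A,1.13,0.59
Monensin,A,1.32,0.68
Puromycin,A,1.31,0.62
Saquinavir,A,1.24,0.45
Chloroquine,B,1.43,0.95
Colchicine,B,1.30,0.86
Domperidone,B,1.33,0.92
Eletriptan,B,1.46,0.94
GSK2,B,1.29,0.86
GSK3,B,1.38,0.97
Indacaterol,B,1.23,0.92
Rh-123,B,1.30,0.82
Salbutamol,B,1.47,0.88
Salmeterol,B,1.60,0.80
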
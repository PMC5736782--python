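name,group,papp_wt_1e6,papp_wt_sd_1e6,papp_ko_1e6,papp_ko_sd_1e6,p_value,ratio
Acrivastine,A,9.17,2.87,14.32,2.88,0.044,1.56
Digoxin,A,6.04,1.46,20.94,2.94,0.0001,3.47
Erythromycin,A,3.02,1.15,13.70,4.54,0.004,4.53
GSK1,A,3.13,1.25,10.57,3.23,0.005,3.38
Mitoxantrone,A,4.69,1.06,13.70,2.69,0.001,2.92
Monensin,A,10.9,1.78,19.06,2.41,0.002,1.74
Puromycin,A,5.83,2.38,14.95,2.33,0.002,2.56
Saquinavir,A,1.56,0.69,15.73,3.52,0.0002,10.07
Chloroquine,B,14.95,2.33,23.39,4.18,0.012,1.56
Colchicine,B,6.93,3.15,14.95,3.18,0.012,2.16
Domperidone,B,10.78,1.77,25.42,8.04,0.012,2.36
Eletriptan,B,4.90,2.51,11.04,2.17,0.010,2.26
GSK2,B,8.18,2.33,17.50,2.91,0.002,2.14
GSK3,B,12.2,2.25,15.31,2.25,0.102,1.25
Indacaterol,B,15.2,2.79,29.22,4.40,0.002,1.92
Rh-123,B,9.06,1.81,22.55,2.24,0.0001,2.49
Salbutamol,B,10.6,2.30,14.90,2.16,0.034,1.41
Salmeterol,B,15.8,2.16,18.33,2.38,0.170,1.16
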
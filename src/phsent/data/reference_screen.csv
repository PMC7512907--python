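rank,measure,p_value,age_cc
1,SampEn_Ener_s1,1.49e-5,-0.30
2,FuzzyEn_Ener_s1,2.12e-5,-0.29
3,FMEn_Ener_s1,6.42e-6,-0.33
4,SampEn_ShanEner_s2,5.88e-5,-0.28
5,FuzzyEn_ShanEner_s2,6.57e-5,-0.27
6,FMEn_ShanEner_s2,1.29e-4,-0.26
7,SampEn_Max_f_s1,7.25e-4,0.21
8,FuzzyEn_Max_f_s1,3.52e-3,0.14
9,FMEn_Max_f_s1,6.47e-3,0.16
10,SampEn_Car_cycle,4.90e-3,-0.31
11,FuzzyEn_Car_cycle,3.99e-3,-0.30
12,FMEn_Car_cycle,1.89e-3,-0.33
13,SampEn_Max_pow_s2,1.20e-9,-0.41
14,FuzzyEn_Max_pow_s2,2.69e-9,-0.39
15,FMEn_Max_pow_s2,6.13e-9,-0.39
16,SampEn_Max_f_s2,8.02e-7,0.43
17,FuzzyEn_Max_f_s2,4.27e-5,0.39
18,SampEn_ShanEner_s1,9.79e-7,-0.37
19,FuzzyEn_ShanEner_s1,3.67e-6,-0.35
20,FMEn_ShanEner_s1,1.60e-6,-0.38
21,FMEn_Max_f_s2,1.52e-6,0.41
22,SampEn_Ener_s2,1.11e-5,-0.31
23,FuzzyEn_Ener_s2,1.76e-5,-0.31
24,FMEn_Ener_s2,3.36e-5,-0.31
25,SampEn_Max_pow_s1,1.58e-5,-0.40
26,FuzzyEn_Max_pow_s1,1.14e-5,-0.40
27,FMEn_Max_pow_s1,3.91e-6,-0.40
28,SampEn_Int_s2,5.38e-4,0.39
29,FuzzyEn_Int_s2,5.06e-4,0.42
30,FMEn_Int_s2,9.26e-3,0.37
31,SampEn_Int_s1,4.22e-1,0.21
32,FuzzyEn_Int_s1,2.35e-1,0.22
33,FMEn_Int_s1,3.92e-1,0.19
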
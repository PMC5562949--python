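patient_id,age_group,delta_ph,delta_pao2_mmhg,delta_pco2_mmhg
1,neonate,0.46,156,-74
3,neonate,0.22,114,2
4,neonate,0.41,55,-39
6,neonate,0.21,13,-19
12,neonate,0.21,205,-32
13,neonate,0.09,97,-10
14,neonate,0.17,56,19
17,neonate,0.19,140,-14
19,neonate,0.27,55,-20
21,neonate,0.40,95,-12
23,neonate,0.34,52,-46
2,child,0.22,13,-41
5,child,0.54,8,-60
7,child,0.32,23,-40
8,child,0.39,189,-94
9,child,0.21,76,-26
10,child,0.26,175,-9
11,child,0.21,23,-31
15,child,0.25,1,-48
16,child,0.42,18,-51
18,child,0.40,117,-12
20,child,0.26,106,-38
22,child,0.19,287,-14
24,child,0.29,-1,-54
25,child,0.15,251,-2
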
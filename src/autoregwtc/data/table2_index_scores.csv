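patient_id,age_group,autoreg_index_pct,modality,timing,total_score
1,neonate,1.7,ultrasound,During ECMO,0
3,neonate,0.8,MRI,3 days post-ECMO,0
4,neonate,8.7,MRI,4 days post-ECMO,10.5
6,neonate,2.0,MRI,2 days post-ECMO,0
12,neonate,12.0,CT,During ECMO,21
13,neonate,4.0,MRI,2 days post-ECMO,0
14,neonate,3.5,ultrasound,During ECMO,1
17,neonate,2.4,MRI,2 days post-ECMO,11
19,neonate,1.1,MRI,4 days post-ECMO,0
21,neonate,0.6,CT,During ECMO,0
23,neonate,1.2,MRI,23 days post-ECMO,1
2,child,3.1,CT,During ECMO,1
5,child,11.9,CT,During ECMO,10
7,child,2.5,MRI,2 days post-ECMO,4
8,child,1.1,CT,During ECMO,11
9,child,4.1,MRI,5 days post-ECMO,5
10,child,15.3,CT,During ECMO,16.5
11,child,8.0,CT,During ECMO,6
15,child,1.8,MRI,7 days post-ECMO,9
16,child,1.1,CT,During ECMO,4
18,child,14.4,MRI,5 days post-ECMO,9
20,child,4.5,ultrasound,During ECMO,0
22,child,8.4,CT,During ECMO,9
24,child,1.0,MRI,5 days post-ECMO,8
25,child,4.0,MRI,4 days post-ECMO,0
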
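patient_id,age_group,ptt_min_s,ptt_mean_s,ptt_max_s,uh_min_iu_ml,uh_mean_iu_ml,uh_max_iu_ml,inr_min,inr_mean,inr_max
1,neonate,21.7,149.1,200,0.10,0.29,0.94,0.8,1.2,1.9
3,neonate,78,138.9,200,0.16,0.37,0.60,1,1.1,1.2
4,neonate,71.8,101,200,0.10,0.13,0.23,1.4,1.5,1.6
6,neonate,77,146.3,200,0.10,0.28,0.39,1.2,1.4,1.6
12,neonate,33.1,115.1,200,0.10,0.16,0.34,0.9,1.1,1.8
13,neonate,93.8,140.9,172.9,0.24,0.37,0.53,0.9,1.3,1.7
14,neonate,830,138.3,200,0.12,0.48,1.01,1.1,1.2,1.5
17,neonate,72.5,126.4,200,0.10,0.33,1.10,1.4,1.7,2.2
19,neonate,37.8,108.3,200,0.10,0.14,0.30,1.4,2,3.6
21,neonate,74.1,106.4,139.4,0.10,0.14,0.20,1.1,1.6,2.1
23,neonate,136.6,177.7,200,0.11,0.22,0.34,1.5,1.8,2
2,child,52.9,84.9,111.1,0.10,0.43,0.72,0.9,1,1.3
5,child,53.5,88.7,200,0.15,0.33,0.70,1,1.1,1.2
7,child,52.5,85,200,0.17,0.36,0.71,0.9,1.1,1.2
8,child,49.1,74.7,158.3,0.10,0.37,0.94,0.8,1.3,2.2
9,child,35.9,52.3,131.3,0.10,0.29,0.59,0.8,1,1.2
10,child,200,200,200,0.10,0.10,0.10,2.2,2.8,3.6
11,child,38,51.8,70.7,0.10,0.13,0.31,1,1.2,1.6
15,child,54.9,85.9,200,0.24,0.31,0.36,1,1.1,1.3
16,child,56.7,102.1,154.9,0.10,0.27,0.48,1,1.1,1.5
18,child,58.1,102.7,200,0.10,0.30,0.52,1,1.4,2.6
20,child,35.4,92.9,200,0.10,0.21,0.56,1,1.3,2.7
22,child,85.3,130,200,0.12,0.18,0.23,1.5,1.6,1.7
24,child,37.8,70,131.5,0.10,0.14,0.20,0.9,1,1.2
25,child,57,66.3,78,0.11,0.19,0.27,1.1,1.4,1.8
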
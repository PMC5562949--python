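patient_id,age_group,age,sex,diagnosis_primary,diagnosis_secondary,ecmo_type,ecmo_duration_h,survival
1,neonate,<1 week,F,PPHN,CDH,VA,545,no
3,neonate,<1 week,F,PPHN,Meconium aspiration,VA,102,yes
4,neonate,<1 week,F,PPHN,Meconium aspiration,VA,62,no
6,neonate,<1 week,M,PPHN,Meconium aspiration,VV,75,yes
12,neonate,<1 week,F,ARDS and septic shock,Adenovirus,VV_TO_VA,263,no
13,neonate,<1 week,F,PPHN,Meconium aspiration,VA,89,yes
14,neonate,<1 week,M,PPHN,Neonatal lung disease,VA,112,yes
17,neonate,<1 week,M,PPHN,Septic shock,VA,56,yes
19,neonate,<1 week,M,PPHN,Meconium aspiration,VA,58,yes
21,neonate,<1 week,F,PPHN,Meconium aspiration,VA,106,yes
23,neonate,<1 week,F,PPHN,Meconium aspiration,VV,80,yes
2,child,3 months,F,ARDS,Rhinovirus infection,VV,227,no
5,child,8 years,F,ARDS,Pulmonary contusion secondary to trauma,VV,140,yes
7,child,7 months,M,ARDS,Influenza A,VV,346,yes
8,child,10 months,F,Septic shock,HLH and influenza,VV_TO_VA,310,no
9,child,2 years,F,ARDS,RSV and Moraxella pneumonia,VV_TO_VA,938,yes
10,child,14 years,F,Septic shock,Neisseria meningitidis,VA,48,no
11,child,15 years,M,ARDS,Fluid overload and sepsis,VV,368,yes
15,child,14 years,F,ARDS,ALL and BMT,VV,144,yes
16,child,3 months,M,ARDS,Parainfluenza and Haemophilus influenzae,VV_TO_VA,330,yes
18,child,7 years,M,Septic shock,Streptococcus pneumonia,VA,153,yes
20,child,6 weeks,F,ARDS,"Influenza, RSV, Moraxella",VV,396,no
22,child,4 months,F,ARDS,Septic shock and liver failure,VA,71,no
24,child,2 years,F,ARDS,RSV and ALL,VV,550,yes
25,child,6 years,F,Septic shock,ALL,VA,105,yes
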
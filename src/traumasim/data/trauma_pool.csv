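case_id,category,n_injured,injured_elements
97910-SA,sports accident,1,frontal_4
89829-SA,sports accident,3,mandible_L_1;mandible_L_2;mandible_R_4
AE-03,animal encounter,4,parietal_R_1;parietal_R_2;parietal_R_3;parietal_R_4
AE-04,animal encounter,6,parietal_L_1;parietal_L_2;temporal_L_1;temporal_L_2;occipital_1;occipital_3
Case 1,animal encounter,6,zygomatic_R_1;zygomatic_R_2;maxilla_R_1;maxilla_R_2;maxilla_R_3;maxilla_R_4
Case 2,animal encounter,5,zygomatic_L_1;zygomatic_L_2;maxilla_L_1;maxilla_L_2;maxilla_L_4
Case 3,animal encounter,9,mandible_L_1;mandible_L_4;zygomatic_L_1;zygomatic_L_2;maxilla_L_1;maxilla_L_2;maxilla_L_3;maxilla_L_4;maxilla_R_1
44849,animal encounter,9,frontal_2;maxilla_R_1;maxilla_R_2;maxilla_R_3;maxilla_R_4;nasal_R_1;nasal_R_2;zygomatic_R_1;zygomatic_R_2
187674,fall from a height,1,occipital_4
56134,fall from a height,2,mandible_R_1;mandible_R_4
FT-1,fall from a height,34,frontal_1;frontal_2;frontal_3;frontal_4;parietal_L_1;parietal_L_2;parietal_R_1;parietal_R_2;parietal_R_3;temporal_L_1;temporal_L_2;temporal_R_1;temporal_R_2;occipital_1;occipital_2;maxilla_L_1;maxilla_L_2;maxilla_L_3;maxilla_L_4;maxilla_R_1;maxilla_R_2;maxilla_R_3;zygomatic_L_1;zygomatic_L_2;zygomatic_R_1;nasal_L_1;nasal_L_2;nasal_R_1;mandible_L_1;mandible_L_2;mandible_L_3;mandible_L_4;mandible_R_1;mandible_R_2
FT-2,fall from a height,3,mandible_L_1;mandible_L_2;mandible_R_2
FT-3,fall from a height,1,maxilla_L_1
FT-4,fall from a height,19,frontal_1;frontal_3;parietal_L_1;parietal_L_2;parietal_L_3;parietal_L_4;temporal_L_1;temporal_L_2;occipital_1;maxilla_L_1;maxilla_L_2;maxilla_L_3;maxilla_L_4;zygomatic_L_1;zygomatic_L_2;nasal_L_1;nasal_L_2;mandible_L_1;mandible_L_2
FT-12,fall from a height,8,temporal_L_1;temporal_L_2;temporal_R_1;temporal_R_2;parietal_L_3;parietal_R_3;occipital_1;occipital_2
FT-14,fall from a height,4,temporal_R_1;parietal_R_1;parietal_R_3;occipital_2
FT-8,fall from a height,4,frontal_1;frontal_3;maxilla_L_1;maxilla_L_2
FT-16,fall from a height,8,frontal_1;frontal_2;occipital_1;occipital_3;parietal_L_1;parietal_L_2;maxilla_L_1;maxilla_L_2
23979,fall from a height,4,frontal_2;frontal_4;parietal_R_1;parietal_R_2
88120,miscellaneous clinical,3,temporal_R_1;temporal_R_4;mandible_R_4
91256,miscellaneous clinical,2,nasal_L_1;nasal_R_1
90655,miscellaneous clinical,2,frontal_1;frontal_2
68197,miscellaneous clinical,2,nasal_L_2;nasal_R_2
13084,miscellaneous clinical,1,parietal_L_2
73267,projectile/arrow shot,1,mandible_L_3
72101,projectile/arrow shot,1,frontal_2
BFT-2,violence,2,parietal_R_1;parietal_R_2
BFT-3,violence,4,occipital_1;occipital_4;temporal_L_2;temporal_L_3
BFT-8,violence,19,frontal_1;frontal_2;frontal_3;frontal_4;nasal_L_1;nasal_L_2;nasal_R_1;nasal_R_2;zygomatic_L_1;zygomatic_L_2;zygomatic_R_1;zygomatic_R_2;maxilla_L_1;maxilla_L_2;maxilla_L_3;maxilla_L_4;maxilla_R_1;maxilla_R_2;mandible_L_1
BFT-10,violence,5,zygomatic_L_1;zygomatic_L_2;maxilla_L_1;maxilla_L_2;maxilla_L_3
BFT-15,violence,19,frontal_1;frontal_3;temporal_L_1;temporal_L_2;temporal_L_3;temporal_L_4;nasal_L_1;nasal_L_2;nasal_R_1;nasal_R_2;mandible_L_1;mandible_L_2;mandible_L_3;mandible_L_4;mandible_R_1;maxilla_L_1;maxilla_L_2;maxilla_L_3;maxilla_L_4
155152,violence,1,mandible_R_4
82151,violence,1,mandible_L_1
57289,violence,2,mandible_L_1;mandible_L_2
54433,violence,4,mandible_R_1;mandible_R_2;mandible_L_1;mandible_L_2
48597,violence,2,zygomatic_L_1;zygomatic_L_2
47820,violence,1,zygomatic_R_2
97910-V,violence,1,maxilla_R_1
89829-V,violence,4,nasal_L_1;nasal_L_2;nasal_R_1;maxilla_L_1
V-40,violence,3,temporal_R_1;parietal_R_1;parietal_R_2
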
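bone,ess
frontal,20.0
parietal_L,19.0
parietal_R,19.0
temporal_L,15.0
temporal_R,15.0
occipital,16.0
maxilla_L,8.0
maxilla_R,8.0
zygomatic_L,5.0
zygomatic_R,5.0
nasal_L,3.0
nasal_R,3.0
mandible_L,21.0
mandible_R,21.0
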
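name,alpha,beta
default,0.1,0.05
ptv_gbm_cavity,0.035,0.0167
ptv_lung_sbrt,0.3,0.03
ptv_sarcoma_metastasis,0.0585,0.0195
ptv_breast,0.1025,0.02631
PTV,0.035,0.0167
brain_stem,0.035,0.0167
cochlea,0.035,0.0167
chiasm,0.0251,0.0084
optic_nerve,0.0497,0.0166
spinal_cord,0.0307,0.0081
pituitary_gland,0.035,0.0167
brain,0.035,0.0167
parotid_gland,0.0341,0.0114
lens,0.0544,0.0543
heart,0.0579,0.029
trachea,0.1,0.05
aorta,0.1,0.05
esophagus,0.0585,0.0195
lung,0.0307,0.0081
myelon,0.0307,0.0153
stomach_small_bowel,0.0895,0.0128
kidney,0.0106,0.0036
eye,0.1,0.05
liver,0.0683,0.0455
breast_contralateral,0.3,0.0882
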
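plan,structure,metric,threshold,comparator
gbm_cavity,brain_stem,Dmax,54,<
gbm_cavity,cochlea,Dmax,45,<
gbm_cavity,chiasm,Dmax,55,<
gbm_cavity,optic_nerve_r,Dmax,55,<
gbm_cavity,optic_nerve_l,Dmax,55,<
gbm_cavity,spinal_cord,Dmax,50,<
gbm_cavity,pituitary_gland,Dmax,45,<
gbm_cavity,brain_without_ptv,Dmean,30,<
gbm_cavity,parotid_gland_l,Dmean,26,<
gbm_cavity,lens_l,Dmax,5,<
lung_sbrt,heart,Dmax,26,<
lung_sbrt,trachea,Dmax,32,<
lung_sbrt,aorta,Dmax,45,<
lung_sbrt,esophagus,Dmean,34,<
lung_sbrt,lung_total,V20Gy,20,<
lung_sbrt,lung_ipsilateral,Dmean,7,<
bone_metastasis,lung_ipsilateral,Dmean,7,<
bone_metastasis,myelon,Dmax,45,<
bone_metastasis,lung_total,V20Gy,20,<
bone_metastasis,heart,Dmean,26,<
bone_metastasis,stomach_small_bowel,D150cc,30,<
bone_metastasis,kidney_ipsilateral,V50%,14,<
bone_metastasis,esophagus,Dmean,30,<
brain_metastasis_rs,brain_stem,Dmax,54,<
brain_metastasis_rs,optic_nerve_l,Dmax,55,<
brain_metastasis_rs,myelon,Dmax,50,<
brain_metastasis_rs,brain_minus_gtv,Dmax,60,<
brain_metastasis_rs,lens_l,Dmax,5,<
brain_metastasis_rs,eye_l,Dmax,45,<
breast_hypofractionated,lung_total,V20Gy,20,<
breast_hypofractionated,lung_ipsilateral,Dmean,7,<
breast_hypofractionated,heart,Dmean,4,<
breast_hypofractionated,liver,Dmean,30,<
breast_hypofractionated,myelon,Dmax,40,<
breast_hypofractionated,breast_contralateral,Dmax,2.64,<
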
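Precentral_L	SMN
Precentral_R	SMN
Frontal_Sup_L	FPN
Frontal_Sup_R	FPN
Frontal_Sup_Orb_L	DMN
Frontal_Sup_Orb_R	DMN
Frontal_Mid_L	FPN
Frontal_Mid_R	FPN
Frontal_Mid_Orb_L	DMN
Frontal_Mid_Orb_R	DMN
Frontal_Inf_Oper_L	FPN
Frontal_Inf_Oper_R	FPN
Frontal_Inf_Tri_L	FPN
Frontal_Inf_Tri_R	FPN
Frontal_Inf_Orb_L	DMN
Frontal_Inf_Orb_R	DMN
Rolandic_Oper_L	SMN
Rolandic_Oper_R	SMN
Supp_Motor_Area_L	SMN
Supp_Motor_Area_R	SMN
Olfactory_L	DMN
Olfactory_R	DMN
Frontal_Sup_Medial_L	DMN
Frontal_Sup_Medial_R	DMN
Frontal_Med_Orb_L	DMN
Frontal_Med_Orb_R	DMN
Rectus_L	DMN
Rectus_R	DMN
Insula_L	FPN
Insula_R	FPN
Cingulum_Ant_L	DMN
Cingulum_Ant_R	DMN
Cingulum_Mid_L	DMN
Cingulum_Mid_R	DMN
Cingulum_Post_L	DMN
Cingulum_Post_R	DMN
Hippocampus_L	SN
Hippocampus_R	SN
ParaHippocampal_L	DMN
ParaHippocampal_R	DMN
Amygdala_L	SN
Amygdala_R	SN
Calcarine_L	VN
Calcarine_R	VN
Cuneus_L	VN
Cuneus_R	VN
Lingual_L	VN
Lingual_R	VN
Occipital_Sup_L	VN
Occipital_Sup_R	VN
Occipital_Mid_L	VN
Occipital_Mid_R	VN
Occipital_Inf_L	VN
Occipital_Inf_R	VN
Fusiform_L	VN
Fusiform_R	VN
Postcentral_L	SMN
Postcentral_R	SMN
Parietal_Sup_L	FPN
Parietal_Sup_R	FPN
Parietal_Inf_L	FPN
Parietal_Inf_R	FPN
SupraMarginal_L	SMN
SupraMarginal_R	SMN
Angular_L	DMN
Angular_R	DMN
Precuneus_L	DMN
Precuneus_R	DMN
Paracentral_Lobule_L	SMN
Paracentral_Lobule_R	SMN
Caudate_L	SN
Caudate_R	SN
Putamen_L	SN
Putamen_R	SN
Pallidum_L	SN
Pallidum_R	SN
Thalamus_L	SN
Thalamus_R	SN
Heschl_L	SMN
Heschl_R	SMN
Temporal_Sup_L	SMN
Temporal_Sup_R	SMN
Temporal_Pole_Sup_L	DMN
Temporal_Pole_Sup_R	DMN
Temporal_Mid_L	DMN
Temporal_Mid_R	DMN
Temporal_Pole_Mid_L	DMN
Temporal_Pole_Mid_R	DMN
Temporal_Inf_L	VN
Temporal_Inf_R	VN
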
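name	network
Precentral_L	motor
Precentral_R	motor
Postcentral_L	motor
Postcentral_R	motor
Supp_Motor_Area_L	motor
Supp_Motor_Area_R	motor
Paracentral_Lobule_L	motor
Paracentral_Lobule_R	motor
Rolandic_Oper_L	motor
Rolandic_Oper_R	motor
Frontal_Sup_L	CEN
Frontal_Sup_R	CEN
Frontal_Mid_L	CEN
Frontal_Mid_R	CEN
Frontal_Inf_Tri_L	CEN
Frontal_Inf_Tri_R	CEN
Parietal_Sup_L	CEN
Parietal_Sup_R	CEN
Parietal_Inf_L	CEN
Parietal_Inf_R	CEN
Frontal_Sup_Medial_L	DMN
Frontal_Sup_Medial_R	DMN
Frontal_Med_Orb_L	DMN
Frontal_Med_Orb_R	DMN
Cingulum_Post_L	DMN
Cingulum_Post_R	DMN
Precuneus_L	DMN
Precuneus_R	DMN
Angular_L	DMN
Angular_R	DMN
Temporal_Mid_L	DMN
Temporal_Mid_R	DMN
Hippocampus_L	DMN
Hippocampus_R	DMN
ParaHippocampal_L	DMN
ParaHippocampal_R	DMN
Insula_L	salience
Insula_R	salience
Cingulum_Ant_L	salience
Cingulum_Ant_R	salience
Cingulum_Mid_L	salience
Cingulum_Mid_R	salience
Frontal_Inf_Oper_L	salience
Frontal_Inf_Oper_R	salience
SupraMarginal_L	salience
SupraMarginal_R	salience
Calcarine_L	visual
Calcarine_R	visual
Cuneus_L	visual
Cuneus_R	visual
Lingual_L	visual
Lingual_R	visual
Occipital_Sup_L	visual
Occipital_Sup_R	visual
Occipital_Mid_L	visual
Occipital_Mid_R	visual
Occipital_Inf_L	visual
Occipital_Inf_R	visual
Fusiform_L	visual
Fusiform_R	visual
Heschl_L	auditory
Heschl_R	auditory
Temporal_Sup_L	auditory
Temporal_Sup_R	auditory
Caudate_L	basal ganglia
Caudate_R	basal ganglia
Putamen_L	basal ganglia
Putamen_R	basal ganglia
Pallidum_L	basal ganglia
Pallidum_R	basal ganglia
Thalamus_L	basal ganglia
Thalamus_R	basal ganglia
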
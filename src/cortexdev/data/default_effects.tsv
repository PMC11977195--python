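metric	network	beta_age	beta_sex	r2_target	baseline_mean	baseline_sd	role
f_neurite	visual	0.728011	0.0	0.53	0.35	0.03	direct
v_ic	visual	0.678233	0.0	0.46	0.5	0.06	direct
ODI	visual	0.648074	0.0	0.42	0.45	0.05	direct
R_soma	visual	-0.69282	0.0	0.48	11.0	0.7	direct
FA	visual	-0.519615	0.0	0.27	0.2	0.03	direct
SA	visual	0.0	0.0	0.0	20000	2000	direct
f_neurite	somatomotor	0.728011	0.0	0.53	0.35	0.03	direct
v_ic	somatomotor	0.678233	0.0	0.46	0.5	0.06	direct
ODI	somatomotor	0.648074	0.0	0.42	0.45	0.05	direct
R_soma	somatomotor	-0.69282	0.0	0.48	11.0	0.7	direct
FA	somatomotor	-0.519615	0.0	0.27	0.2	0.03	direct
SA	somatomotor	0.0	0.0	0.0	20000	2000	direct
f_neurite	dorsal_attention	0.728011	0.0	0.53	0.35	0.03	direct
v_ic	dorsal_attention	0.678233	0.0	0.46	0.5	0.06	direct
ODI	dorsal_attention	0.648074	0.0	0.42	0.45	0.05	direct
R_soma	dorsal_attention	-0.69282	0.0	0.48	11.0	0.7	direct
FA	dorsal_attention	-0.519615	0.0	0.27	0.2	0.03	direct
SA	dorsal_attention	0.0	0.0	0.0	20000	2000	direct
f_neurite	ventral_attention	0.728011	0.0	0.53	0.35	0.03	direct
v_ic	ventral_attention	0.678233	0.0	0.46	0.5	0.06	direct
ODI	ventral_attention	0.648074	0.0	0.42	0.45	0.05	direct
R_soma	ventral_attention	-0.69282	0.0	0.48	11.0	0.7	direct
FA	ventral_attention	-0.519615	0.0	0.27	0.2	0.03	direct
SA	ventral_attention	0.0	0.0	0.0	20000	2000	direct
f_neurite	limbic	0.728011	0.0	0.53	0.35	0.03	direct
v_ic	limbic	0.678233	0.0	0.46	0.5	0.06	direct
ODI	limbic	0.648074	0.0	0.42	0.45	0.05	direct
R_soma	limbic	-0.69282	0.0	0.48	11.0	0.7	direct
FA	limbic	0.0	0.0	0.0	0.2	0.03	direct
SA	limbic	0.0	0.0	0.0	20000	2000	direct
f_neurite	frontoparietal	0.728011	0.0	0.53	0.35	0.03	direct
v_ic	frontoparietal	0.678233	0.0	0.46	0.5	0.06	direct
ODI	frontoparietal	0.648074	0.0	0.42	0.45	0.05	direct
R_soma	frontoparietal	-0.69282	0.0	0.48	11.0	0.7	direct
FA	frontoparietal	-0.519615	0.0	0.27	0.2	0.03	direct
SA	frontoparietal	0.0	0.0	0.0	20000	2000	direct
f_neurite	default_mode	0.728011	0.0	0.53	0.35	0.03	direct
v_ic	default_mode	0.678233	0.0	0.46	0.5	0.06	direct
ODI	default_mode	0.648074	0.0	0.42	0.45	0.05	direct
R_soma	default_mode	-0.69282	0.0	0.48	11.0	0.7	direct
FA	default_mode	-0.519615	0.0	0.27	0.2	0.03	direct
SA	default_mode	0.0	0.0	0.0	20000	2000	direct
MD	visual	0.0	0.0	0.0	0.85	0.05	direct
MD	somatomotor	0.34	0.0	0.1156	0.85	0.05	direct
MD	dorsal_attention	0.0	0.0	0.0	0.85	0.05	direct
MD	ventral_attention	0.0	0.0	0.0	0.85	0.05	direct
MD	limbic	-0.42	0.0	0.1764	0.85	0.05	direct
MD	frontoparietal	0.0	0.0	0.0	0.85	0.05	direct
MD	default_mode	0.0	0.0	0.0	0.85	0.05	direct
CTh	visual	-0.61	0.0	0.3721	2.8	0.15	direct
CTh	somatomotor	-0.4	0.0	0.16	2.8	0.15	direct
CTh	dorsal_attention	-0.4	0.0	0.16	2.8	0.15	direct
CTh	ventral_attention	0.0	0.0	0.0	2.8	0.15	direct
CTh	limbic	0.0	0.0	0.0	2.8	0.15	direct
CTh	frontoparietal	0.0	0.0	0.0	2.8	0.15	direct
CTh	default_mode	-0.59	0.0	0.3481	2.8	0.15	direct
GMvol	visual	-0.29	0.0	0.0841	60000	6000	direct
GMvol	somatomotor	0.0	0.0	0.0	60000	6000	direct
GMvol	dorsal_attention	-0.34	0.0	0.1156	60000	6000	direct
GMvol	ventral_attention	0.0	0.0	0.0	60000	6000	direct
GMvol	limbic	0.0	0.0	0.0	60000	6000	direct
GMvol	frontoparietal	0.0	0.0	0.0	60000	6000	direct
GMvol	default_mode	-0.37	0.0	0.1369	60000	6000	direct
f_soma	visual	0.0	0.0	0.0	0.35	0.03	direct
f_soma	somatomotor	-0.479583	0.0	0.23	0.35	0.03	direct
f_soma	dorsal_attention	-0.34641	0.0	0.12	0.35	0.03	direct
f_soma	ventral_attention	0.0	0.0	0.0	0.35	0.03	direct
f_soma	limbic	-0.3	0.0	0.09	0.35	0.03	direct
f_soma	frontoparietal	0.0	0.0	0.0	0.35	0.03	direct
f_soma	default_mode	0.0	0.0	0.0	0.35	0.03	direct
f_extracellular	visual	-0.3	0.0	0.09	0.3	0.03	implied
f_extracellular	somatomotor	0.0	0.0	0.0	0.3	0.03	implied
f_extracellular	dorsal_attention	0.0	0.0	0.0	0.3	0.03	implied
f_extracellular	ventral_attention	0.0	0.0	0.0	0.3	0.03	implied
f_extracellular	limbic	-0.458258	0.0	0.21	0.3	0.03	implied
f_extracellular	frontoparietal	0.0	0.0	0.0	0.3	0.03	implied
f_extracellular	default_mode	-0.34641	0.0	0.12	0.3	0.03	implied
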
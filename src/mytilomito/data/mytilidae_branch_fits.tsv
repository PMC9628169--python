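gene	lnL_one_ratio	omega_one_ratio	lnL_three_ratios	omega_shallow	omega_deep	omega_freshwater
atp6	-9059.97	0.0147	-9048.60	0.0051	0.0227	0.1179
cox1	-25065.71	0.0047	-25058.99	0.0061	0.0024	0.0050
cox2	-8952.85	0.0024	-8952.57	0.0025	0.0019	0.0175
cox3	-15865.81	0.0131	-15863.72	0.0163	0.0102	0.0031
cob	-21708.21	0.0207	-21677.83	0.0109	0.0344	0.0028
nad1	-15212.85	0.0244	-15212.24	0.0236	0.0262	0.0107
nad2	-17841.44	0.0433	-17831.67	0.0336	0.0591	0.0048
nad3	-5483.56	0.0225	-5482.37	0.0186	0.0284	0.0025
nad4	-21382.34	0.0370	-21381.96	0.0366	0.0376	0.0024
nad4L	-4847.06	0.0312	-4846.12	0.0283	0.0371	0.0035
nad5	-35424.55	0.0435	-35414.81	0.0366	0.0528	0.0028
nad6	-6775.67	0.0255	-6772.78	0.0213	0.0333	0.0034
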
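trait	group	mean	se	n
initial_weight_kg	bull	275.90	5.62	10
initial_weight_kg	steer	269.10	3.18	10
carcass_weight_kg	bull	455.40	7.82	10
carcass_weight_kg	steer	434.50	5.88	10
rib_eye_area_cm2	bull	91.00	2.74	10
rib_eye_area_cm2	steer	76.10	2.93	10
marbling_score	bull	2.30	0.15	10
marbling_score	steer	3.10	0.22	10
shear_force	bull	3.62	0.56	10
shear_force	steer	3.57	0.51	10
water_pct	bull	72.67	1.14	10
water_pct	steer	67.49	1.48	10
imf_pct	bull	7.04	0.69	10
imf_pct	steer	12.29	1.90	10
protein_pct	bull	20.59	0.40	10
protein_pct	steer	19.53	0.41	10
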
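country	latitude	longitude	radiation_MJ_m2_yr	precipitation_mm_yr	t_mean_C	t_min_C	t_max_C
Czech Republic	50.25	17.25	3295	1127	8.8	-15.8	34.7
Hungary	46.75	16.75	4031	758	13.4	-11.2	38.8
Netherlands	52.25	5.25	3333	876	11.3	-7.1	34.1
Romania	45.25	23.25	3971	836	10.7	-14.6	34.4
Spain	42.75	1.75	4630	989	10.2	-9.5	31.8
Sweden	56.25	14.25	3368	720	8.9	-10.9	31.5
Switzerland	46.75	6.75	3775	1304	10.7	-10.3	33.5
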
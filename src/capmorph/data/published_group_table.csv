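group,n_subjects,n_capillaries,nucleus_area_density_mean,nucleus_area_density_sd,luminal_enlargement_mean,luminal_enlargement_sd,disrupted_bm_mean,disrupted_bm_sd
endurance_pre,10,400,16.9,5.1,13.8,3.5,24.1,9.0
endurance_post,10,400,16.2,6.7,15.2,1.6,25.6,6.2
ar_pre,6,240,15.5,5.0,14.3,4.8,25.6,8.3
ar_post,6,240,17.7,6.4,13.0,3.1,24.6,8.1
nr_pre,6,240,18.4,5.7,13.8,3.5,21.5,5.4
nr_post,6,240,16.3,2.1,13.1,2.1,26.0,8.9
normotensive_pre,10,400,12.9,5.2,14.0,2.7,25.3,5.4
normotensive_post,10,400,14.5,6.0,16.9,2.4,24.9,9.9
hypertensive_pre,9,360,15.6,6.7,15.8,4.1,33.6,5.8
hypertensive_post,9,360,13.6,4.7,13.7,3.6,37.0,7.3
diabetic_pre,10,400,19.2,5.2,10.2,3.1,34.9,8.5
diabetic_post,10,400,17.0,5.4,13.7,1.9,45.7,9.9
ic_control,10,383,12.5,6.4,13.6,2.7,28.5,9.8
ic_pad,14,537,14.2,6.2,12.4,2.6,27.9,6.6
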
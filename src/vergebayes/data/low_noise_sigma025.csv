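# synthetic distance-matching dataset 'low_noise_sigma025'
# generator: vergebayes.synthetic_data.generate_dataset
# sigma_true_deg=0.25 trials_per_distance=2000 report_noise_sd=0.0 summary=peak seed=25
distance_cm,estimate_cm,sd_cm
20.000000,19.837181,0.551992
30.000000,29.671073,1.248121
40.000000,39.647945,2.085288
50.000000,48.944119,3.345099
60.000000,58.950975,4.815553
70.000000,68.230109,6.315428
80.000000,76.151601,8.253799
90.000000,86.560001,10.648917
100.000000,95.128942,12.735308
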
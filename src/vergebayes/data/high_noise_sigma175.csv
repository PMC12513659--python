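# synthetic distance-matching dataset 'high_noise_sigma175'
# generator: vergebayes.synthetic_data.generate_dataset
# sigma_true_deg=1.75 trials_per_distance=2000 report_noise_sd=0.0 summary=peak seed=175
distance_cm,estimate_cm,sd_cm
20.000000,18.359203,3.541360
30.000000,24.602902,6.719188
40.000000,29.334094,9.914370
50.000000,33.218311,11.741692
60.000000,36.484366,12.636709
70.000000,39.380053,12.911224
80.000000,41.811735,13.240894
90.000000,40.965224,13.342264
100.000000,45.920103,13.025912
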
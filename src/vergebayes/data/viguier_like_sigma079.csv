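# synthetic distance-matching dataset 'viguier_like_sigma079'
# generator: vergebayes.synthetic_data.generate_dataset
# sigma_true_deg=0.79 trials_per_distance=2000 report_noise_sd=0.0 summary=peak seed=79
distance_cm,estimate_cm,sd_cm
20.000000,19.333796,1.683019
30.000000,28.252818,3.652171
40.000000,37.193636,6.260749
50.000000,43.127251,9.123738
60.000000,50.216781,13.732801
70.000000,58.672739,16.579646
80.000000,60.781756,19.203620
90.000000,67.618115,22.185158
100.000000,72.023849,24.298041
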
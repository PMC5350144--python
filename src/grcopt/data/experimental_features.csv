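feature,stimulus_pA,exp_mean,exp_sd,model_mean,model_sd
resting_voltage,10,-68.5,12.5,-64.0,0.5
AP_height,10,20.93,1.58,24.59,9.22
AP_width,10,0.67,0.06,0.62,0.02
AP_half_width,10,0.54,0.07,0.49,0.18
AHP_depth,10,-59.21,0.6,-63.0,0.4
AHP_depth_slow,10,-52.69,2.0,-50.96,2.2
time_to_first_spike,10,31.9,16.2,70.56,25.97
mean_frequency,10,30.0,16.2,12.795,5.16
adaptation_index,10,0.1,0.1,0.2,0.3
ISI_CV,10,0.2,0.19,0.2,0.2
resting_voltage,16,-68.77,11.68,-62.69,0.44
AP_height,16,19.25,1.5,31.43,1.61
AP_width,16,0.69,0.05,0.69,0.02
AP_half_width,16,0.55,0.067,0.51,0.01
AHP_depth,16,-58.3,0.6,-62.69,0.44
AHP_depth_slow,16,-48.93,5.1,-55.56,0.62
time_to_first_spike,16,19.0,11.2,8.47,3.67
mean_frequency,16,45.0,21.2,56.95,5.43
adaptation_index,16,0.3,0.3,0.6,0.2
ISI_CV,16,0.2,0.1,0.1,0.3
resting_voltage,22,-69.13,11.67,-61.41,0.5
AP_height,22,17.7,1.85,33.59,1.32
AP_width,22,0.71,0.06,0.7,0.02
AP_half_width,22,0.58,0.07,0.49,0.01
AHP_depth,22,-57.19,0.7,-61.41,0.49
AHP_depth_slow,22,-32.7,12.1,-50.28,0.75
time_to_first_spike,22,14.65,9.4,4.25,2.78
mean_frequency,22,60.0,39.4,95.09,5.37
adaptation_index,22,0.3,0.03,0.1,0.05
ISI_CV,22,0.2,0.1,0.5,0.1
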
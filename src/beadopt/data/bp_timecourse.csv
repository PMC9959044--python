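group,time_label,time_h,bp_mean_mmhg,bp_sd_mmhg
control,initial,0,125,1.5
control,1,1,124,2.6
control,2,2,125,1.7
control,3,3,124,2.4
control,4,4,125,1.2
control,5,5,123,0.6
control,6,6,125,1.0
control,7,7,124,1.9
control,8,8,126,1.4
control,10,10,122,1.7
control,12,12,125,1.7
positive_control,initial,0,167,1.2
positive_control,1,1,163,2.6
positive_control,2,2,162,1.9
positive_control,3,3,165,1.3
positive_control,4,4,164,3.2
positive_control,5,5,163,3.1
positive_control,6,6,165,2.4
positive_control,7,7,166,1.8
positive_control,8,8,167,4.2
positive_control,10,10,167,2.3
positive_control,12,12,168,3.1
standard_tel,initial,0,165,3.4
standard_tel,1,1,123,1.2
standard_tel,2,2,110,4.0
standard_tel,3,3,134,3.5
standard_tel,4,4,151,2.8
standard_tel,5,5,161,2.3
standard_tel,6,6,164,1.4
standard_tel,7,7,166,3.1
standard_tel,8,8,167,4.5
standard_tel,10,10,166,2.6
standard_tel,12,12,169,1.6
op2_beads,initial,0,169,3.2
op2_beads,1,1,160,1.5
op2_beads,2,2,149,2.6
op2_beads,3,3,135,2.5
op2_beads,4,4,131,4.1
op2_beads,5,5,128,5.1
op2_beads,6,6,120,6.3
op2_beads,7,7,138,3.9
op2_beads,8,8,149,1.3
op2_beads,10,10,165,4.1
op2_beads,12,12,166,1.9
op1_beads,initial,0,166,1.5
op1_beads,1,1,131,3.1
op1_beads,2,2,124,3.1
op1_beads,3,3,119,4.1
op1_beads,4,4,106,2.3
op1_beads,5,5,98,3.2
op1_beads,6,6,91,1.9
op1_beads,7,7,88,3.2
op1_beads,8,8,101,6.3
op1_beads,10,10,109,6.4
op1_beads,12,12,116,7.2
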
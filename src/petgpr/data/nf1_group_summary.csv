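measure,mean1,sd1,n1,mean2,sd2,n2
Age,25.56,16.94,16,23.75,11.77,16
Education,9.06,4.07,16,8.69,4.05,16
SES,22.50,5.85,16,18.94,7.02,16
IQ,107.81,5.64,16,91.19,15.28,16
VIQ,108.44,6.38,16,92.44,15.40,16
PIQ,107.19,6.88,16,91.13,15.27,16
NHPT_dom,0.79,0.23,16,0.89,0.30,16
NHPT_nondom,0.87,0.33,16,0.91,0.20,16
ROCF_copy,30.38,6.21,16,26.81,8.36,16
RAVLT_A6,10.06,3.60,16,8.31,2.57,16
RAVLT_A7,9.06,3.00,16,8.63,2.50,16
ROCF_immediate,17.94,6.83,16,12.94,9.14,16
ROCF_delayed,17.06,6.34,16,14.19,6.77,16
VFT_semantic,15.63,3.56,16,15.00,5.19,16
VFT_FAS,29.75,13.98,16,27.25,12.50,16
FDT_decoding,25.44,8.73,16,26.81,7.09,16
FDT_inhibiting,53.19,23.93,16,52.19,14.53,16
DST_fwd,56.81,27.26,16,28.38,12.50,16
DST_bwd,18.75,11.54,16,18.81,10.09,16
CBTT_fwd,45.75,16.72,16,38.13,21.28,16
CBTT_bwd,36.81,32.44,16,20.38,21.36,16
TOL,29.56,3.16,16,28.69,3.91,16
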
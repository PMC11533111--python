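parameter,man,woman,units,source
BW,73.0,60.0,kg,"reference body weight, European adults"
W_liver,1.898,1.5599999999999998,kg,0.026 * BW
W_blood,5.3,3.9,kg,equal to V_blood (density 1 kg/L)
W_others,65.802,54.54,kg,BW - W_liver - W_blood
QC,6.5,5.9,L/min,reference cardiac output
Q_liver_total,1.6575,1.5930000000000002,L/min,"0.255 * QC (men), 0.270 * QC (women); portal vein + hepatic artery"
Q_others,4.8425,4.307,L/min,QC - Q_liver_total
V_blood,5.3,3.9,L,reference total blood volume
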
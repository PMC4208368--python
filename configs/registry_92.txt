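# Default 92-measure registry (canonical ids; one per line).
# Override via the pipeline config key `registry_path`.
# QS = quiet standing, FC = force control, GA = gait analysis;
# Mn/SD/CV = mean / standard deviation / coefficient of variation.

QS:Mn-DIST-QEO
QS:Mn-DIST-AP-QEO
QS:Mn-DIST-ML-QEO
QS:Mn-RMS-QEO
QS:Mn-RMS-AP-QEO
QS:Mn-RMS-ML-QEO
QS:Mn-VEL-QEO
QS:Mn-VEL-AP-QEO
QS:Mn-VEL-ML-QEO
QS:Mn-FREQ-QEO
QS:Mn-FREQ-AP-QEO
QS:Mn-FREQ-ML-QEO
QS:Mn-AREA-QEO
QS:Mn-EA-QEO
QS:Mn-DIST-QEC
QS:Mn-DIST-AP-QEC
QS:Mn-DIST-ML-QEC
QS:Mn-RMS-QEC
QS:Mn-RMS-AP-QEC
QS:Mn-RMS-ML-QEC
QS:Mn-VEL-QEC
QS:Mn-VEL-AP-QEC
QS:Mn-VEL-ML-QEC
QS:Mn-FREQ-QEC
QS:Mn-FREQ-AP-QEC
QS:Mn-FREQ-ML-QEC
QS:Mn-AREA-QEC
QS:Mn-EA-QEC
FC:Mn-MVIC-KE
FC:Mn-c15-KE
FC:SD-c15-KE
FC:CV-c15-KE
FC:Mn-c20-KE
FC:SD-c20-KE
FC:CV-c20-KE
FC:Mn-r1520-KE
FC:SD-r1520-KE
FC:CV-r1520-KE
FC:Mn-MVIC-PF
FC:Mn-c15-PF
FC:SD-c15-PF
FC:CV-c15-PF
FC:Mn-c20-PF
FC:SD-c20-PF
FC:CV-c20-PF
FC:Mn-r1520-PF
FC:SD-r1520-PF
FC:CV-r1520-PF
GA:Mn-Str-T-L
GA:SD-Str-T-L
GA:CV-Str-T-L
GA:Mn-Str-T-R
GA:SD-Str-T-R
GA:CV-Str-T-R
GA:Mn-Stn-T-L
GA:SD-Stn-T-L
GA:CV-Stn-T-L
GA:Mn-Stn-T-R
GA:SD-Stn-T-R
GA:CV-Stn-T-R
GA:Mn-Sw-T-L
GA:SD-Sw-T-L
GA:CV-Sw-T-L
GA:Mn-Sw-T-R
GA:SD-Sw-T-R
GA:CV-Sw-T-R
GA:Mn-DST-L
GA:SD-DST-L
GA:CV-DST-L
GA:Mn-DST-R
GA:SD-DST-R
GA:CV-DST-R
GA:Mn-Str-Len-L
GA:SD-Str-Len-L
GA:CV-Str-Len-L
GA:Mn-Str-Len-R
GA:SD-Str-Len-R
GA:CV-Str-Len-R
GA:Mn-MaxFC-L
GA:SD-MaxFC-L
GA:CV-MaxFC-L
GA:Mn-MaxFC-R
GA:SD-MaxFC-R
GA:CV-MaxFC-R
GA:Mn-MinFC-L
GA:Mn-MinFC-R
GA:Mn-CAD
GA:SD-CAD
GA:Mn-SW
GA:SD-SW
GA:Mn-Stp-Len
GA:SD-Stp-Len
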
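# Case metrics for five patient-specific anatomies (A-E), each measured on
# the in vitro pulse-duplicator replica and on the matching in silico model.
# Units: co L/min; sv mL/beat; eoa,eroa cm2; closing,leak mL/beat (signed);
# rf %SV; dp_sys,dp_dia mmHg; n_platelets count; pct_pvl,pct_reenter %;
# mean_sa Pa.s. Empty cells: quantity not defined/reported for that setting.
case_id,setting,co,sv,eoa,eroa,closing,leak,rf,dp_sys,dp_dia,n_platelets,pct_pvl,pct_reenter,mean_sa
A,in_vitro,4.71,78.2,1.39,,-2.7,-7.0,12.4,29.7,-86.6,,,,
B,in_vitro,4.90,78.3,1.08,,-3.4,-4.2,9.7,44.4,-86.8,,,,
C,in_vitro,4.75,77.5,1.03,,-2.2,-6.7,11.5,48.2,-88.1,,,,
D,in_vitro,5.20,85.2,1.17,,-4.0,-5.8,11.5,48.2,-88.1,,,,
E,in_vitro,4.94,77.5,1.48,,-2.9,-3.0,7.6,25.4,-82.3,,,,
A,in_silico,4.54,81.2,1.50,0.067,-3.7,-12.7,20.2,29.7,-86.6,2400000,14.7,5.8,3.75
B,in_silico,5.19,79.4,1.05,0.028,-1.3,-3.9,6.6,44.4,-86.8,1900000,6.5,1.5,
C,in_silico,3.54,58.2,0.80,0.034,-1.0,-6.6,13.1,48.2,-88.1,1700000,23.2,5.9,
D,in_silico,5.29,92.2,1.17,0.069,-2.0,-14.6,18.0,48.2,-88.1,3300000,22.3,6.5,3.29
E,in_silico,4.23,70.0,1.22,0.058,-2.6,-8.2,15.4,25.4,-82.3,2600000,22.6,8.1,1.04
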
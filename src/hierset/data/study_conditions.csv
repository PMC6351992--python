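condition,n_downloaded,n_intensional,n_derived,ext_minutes_measured,int_minutes,n_terms_downloaded,n_terms_intensional,only_in_downloaded,exclude_from_summary
CKD-5 and ESRD,5,3,27,17,3,485,586,0,0
Hypertension,12,3,233,,3,131,5473,1,0
Kidney transplant,8,8,36,,15,49,708,6,0
"Pregnancy, narrow",35,6,156,,4,23429,24043,0,0
"Pregnancy, broad",35,20,1262,,12,23429,47812,0,1
Bipolar disorder,99,2,109,,5,1640,1744,0,0
Depression and dysthymia,72,2,151,,5,978,1946,0,0
Personality disorders,26,2,48,,5,401,724,0,0
Diabetes,89,6,441,,6,11997,33707,3,0
Prostate cancer,12,3,19,10,7,,,2,0
Pain related to prostate cancer,17,14,20,12,7,149,149,0,0
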
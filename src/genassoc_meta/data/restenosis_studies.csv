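study_id,year,ethnicity,intervention,followup_months,restenosis_definition,n_cases_total,n_controls_total,mean_age,pct_male,quality
Ohishi 1993,1993,Asian,balloon,6,diameter stenosis >50%,32,50,NA,NA,High
Beohar 1995,1995,Caucasian,balloon,3,diameter stenosis >=50%,64,25,63.9,NA,High
van Bockxmeer 1995,1995,Caucasian,balloon,6,diameter stenosis >50%,88,119,57.0,82.1,High
Kamitani 1995,1995,Asian,balloon,6,diameter stenosis >50%,38,52,52.0,100,High
Kaski 1996,1996,Caucasian,balloon,6,diameter stenosis >=50%,35,34,58.0,82.6,Median
Tsukada 1997,1997,Asian,balloon,3,diameter stenosis >=50%,25,71,60.0,NA,Median
Hamon 1998,1998,Caucasian,balloon,6,diameter stenosis >50%,116,155,60.0,84.5,High
Yoshida 1999,1999,Asian,balloon,62.4,diameter stenosis >=50%,47,123,58.2,NA,High
Okamura 1999,1999,Asian,balloon,6,diameter stenosis >50%,19,27,60.0,86.6,High
Volzke 2000,2000,Caucasian,balloon,6,diameter stenosis >50%,160,351,60.6,75.9,High
Zee 2001,2001,Caucasian,balloon,6,diameter stenosis >50%,342,437,58.9,89.2,High
Samani 1995,1995,Caucasian,balloon,4,diameter stenosis >=50%,110,123,NA,83.3,High
Amant 1997,1997,Caucasian,stent,6,diameter stenosis >50%,59,99,60.0,80.1,High
Gensini 1999,1999,Caucasian,stent,6,diameter stenosis >=50%,27,130,NA,NA,Median
Guarda 1999,1999,Caucasian,stent,6,diameter stenosis >50%,22,26,NA,NA,Median
Gurlek 2000,2000,Caucasian,stent,6,diameter stenosis >=50%,51,107,53.0,84.8,High
Koch 2000,2000,Caucasian,stent,12,diameter stenosis >=50%,513,1043,62.9,78.8,High
Jorgensen 2001,2001,Caucasian,stent,6,diameter stenosis >50%,49,320,59.0,79.4,High
Taniguchi 2001,2001,Asian,stent,6,diameter stenosis >50%,26,41,65.2,74.6,Median
Ferrari 2002,2002,Caucasian,stent,6,diameter stenosis >=50%,39,115,61.0,77.3,High
Ryu 2002,2002,Asian,stent,6,diameter stenosis >50%,64,191,59.5,74.8,High
Gomma 2002,2002,Caucasian,stent,6,diameter stenosis >=50%,60,144,59.4,75.6,High
Qu 2002,2002,Asian,stent,3,diameter stenosis >=50%,43,85,68.0,84.4,Median
Okumura 2002,2002,Asian,stent,6,diameter stenosis >=50%,16,76,64.3,79.3,Median
Ribichini 2003,2003,Caucasian,stent,6.3,diameter stenosis >=50%,271,727,61.0,82.2,High
Guo 2005,2005,Asian,stent,6,diameter stenosis >=50%,30,73,70.0,NA,Median
Wang 2005a,2005,Asian,stent,6,diameter stenosis >=50%,62,40,62.0,88.2,Median
Guneri 2005,2005,Caucasian,stent,9,diameter stenosis >=70%,48,48,59.6,62.8,High
Wang 2005b,2005,Asian,stent,6,diameter stenosis >=50%,58,139,NA,NA,Median
Ujiie 2006,2006,Asian,stent,7,diameter stenosis >50%,15,60,66.9,78.6,Median
Gao 2006,2006,Asian,stent,6,diameter stenosis >=50%,102,247,NA,NA,Median
Wijpkema 2006,2006,Caucasian,stent,9,diameter stenosis >50%,316,2572,62.0,70.9,High
Lv 2012,2012,Asian,stent,6,diameter stenosis >=50%,81,315,58.8,89.4,High
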
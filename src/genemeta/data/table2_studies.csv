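study_id,first_author,year,country,control_source,case_gg,case_ga,case_aa,control_gg,control_ga,control_aa,nos_score
Zhao2014,Zhao,2014,China,HB,194,106,8,194,100,14,7
Li2009,Li,2009,China,PB,101,76,15,114,66,11,8
Zhou2010,Zhou,2010,China,PB,99,91,11,97,91,11,8
Yuan2016,Yuan,2016,China,PB,104,50,7,99,60,2,8
Hidaka2015,Hidaka,2015,Japan,PB,287,149,21,292,150,15,8
Yang2016,Yang,2016,Korea,HB,304,141,5,736,292,22,7
Cao2010,Cao,2010,China,PB,196,161,25,206,155,21,8
Chen2016,Chen,2016,China,HB,133,95,18,163,101,10,7
Zhang2017,Zhang,2017,China,HB,1995,643,48,2663,941,71,7
Matsuo2013,Matsuo,2013,Japan,HB,310,323,63,683,580,109,7
Chang2014,Chang,2014,China,PB,108,76,12,213,160,20,8
Shin2011,Shin,2011,Korea,HB,291,141,13,250,102,18,8
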
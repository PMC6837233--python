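series_id,year,estimate,cv
ABS,2008,14264,0.084
ABS,2012,20389,0.071
FG,1982,45,0.91
FG,1986,259,0.59
FG,1997,200,0.64
BG1,2008,7689,0.08
BG1,2011,8652,0.07
BG1,2015,12123,0.07
BG2,2002,3026,0.13
BG2,2003,2999,0.13
BG2,2004,3763,0.18
BG2,2005,4113,0.09
BG2,2008,5399,0.14
BG2,2011,8832,0.14
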
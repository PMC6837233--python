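name,recent_year,rmax_prior,index_set,include_premodern,allocation,slr_mode,n_floor,z
RC,2008,uniform,FG+BG1,1,core,both_eras,0,2.39
D-1,2012,uniform,FG+BG1,1,core,both_eras,0,2.39
D-2,2008,uniform,,1,core,both_eras,0,2.39
D-3,2008,uniform,FG+BG2,1,core,both_eras,0,2.39
D-4,2008,uniform,BG1,1,core,both_eras,0,2.39
D-5,2008,uniform,BG2,1,core,both_eras,0,2.39
D-6,2008,uniform,FG,1,core,both_eras,0,2.39
D-7,2008,informative,FG+BG1,1,core,both_eras,0,2.39
C-1,2008,uniform,FG+BG1,0,core,none,0,2.39
C-2,2008,uniform,FG+BG1,0,core,both_eras,0,2.39
C-3,2008,uniform,FG+BG1,1,core,none,0,2.39
C-4,2008,uniform,FG+BG1,1,core,C4_split,0,2.39
C-5,2008,uniform,FG+BG1,1,core+falkland,both_eras,0,2.39
C-6,2008,uniform,FG+BG1,1,fringe,both_eras,0,2.39
C-7,2008,uniform,FG+BG1,1,overlap,both_eras,0,2.39
G-1,2008,uniform,FG+BG1,1,core,both_eras,162,2.39
G-2,2008,uniform,FG+BG1,1,core,both_eras,15,2.39
M-1,2008,uniform,FG+BG1,1,core,both_eras,0,5.04
M-2,2008,uniform,FG+BG1,1,core,both_eras,0,11.22
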
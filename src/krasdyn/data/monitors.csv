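name,res1,aa1,res2,aa2,theme,description,mutation_studied
Q61-D92,61,GLN,92,ASP,switch2_helix3_loopout,H-bond between alpha-2 and alpha-3 helices; lost in mutation favoring Switch-2 loop-out,"G12D, WT"
E62-H95,62,GLU,95,HIS,switch2_helix3_loopout,H-bond between alpha-2 and alpha-3 helices; lost in mutation favoring Switch-2 loop-out,"G12D, WT"
A11-Q61,11,ALA,61,GLN,ploop_switch2_coupling,H-bond between p-loop and Switch 2 / alpha-2; lost in mutation favoring loop-out,"G12D, WT"
G12-Q61,12,GLY,61,GLN,ploop_switch2_coupling,H-bond between p-loop and Switch 2 / alpha-2; lost in mutation favoring loop-out,"G12D, WT"
I36-A59,36,ILE,59,ALA,switch1_switch2_coordination,H-bond between beta-2/beta-3 ladder bridging the Switches; mutation decouples Switch 1 and Switch 2,"G12D, G13D, WT"
Y32-Y40,32,TYR,40,TYR,switch1_switch2_coordination,Intra-Switch-1 H-bond and ring stacking; G13D favors intermediates not used by WT,"G12D, G13D, WT"
Y32-A59,32,TYR,59,ALA,switch1_switch2_coordination,Interconnection between Switch 1 and Switch 2; G13D favors A59 replacing the magnesium ion,"G12D, G13D, WT"
G12-T35,12,GLY,35,THR,mg_t35_coordination,T35 in the H-bond network among nucleotide and Q61; network destabilized by mutation,"G12V, Q61L"
Q61-T35,61,GLN,35,THR,mg_t35_coordination,T35 in the H-bond network among nucleotide and Q61; network destabilized by mutation,"G12V, Q61L"
S17-T35,17,SER,35,THR,mg_t35_coordination,Failure to bind the magnesium ion and coordinate T35,"G12V, Q61L"
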
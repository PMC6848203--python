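name,mass,charge,sigma,epsilon
SC_ALA,15.0,0.0,4.2,0.30
SC_VAL,43.1,0.0,4.8,0.40
SC_LEU,57.1,0.0,5.1,0.45
SC_ILE,57.1,0.0,5.1,0.45
SC_PHE,91.1,0.0,5.4,0.50
SC_TRP,130.2,0.0,5.7,0.55
SC_MET,75.2,0.0,5.2,0.45
SC_SER,31.0,0.0,4.2,0.35
SC_THR,45.1,0.0,4.5,0.35
SC_CYS,47.1,0.0,4.5,0.40
SC_ASN,58.1,0.0,4.7,0.40
SC_GLN,72.1,0.0,4.9,0.40
SC_TYR,107.1,0.0,5.5,0.50
SC_LYS,72.2,1.0,5.0,0.35
SC_ARG,100.2,1.0,5.3,0.35
SC_HIS,81.1,0.0,5.0,0.40
SC_ASP,59.0,-1.0,4.6,0.35
SC_GLU,73.1,-1.0,4.8,0.35
SC_PRO,41.1,0.0,4.6,0.35
SC_GLY,15.0,0.0,3.8,0.25
CA,56.0,0.0,4.1,0.25
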
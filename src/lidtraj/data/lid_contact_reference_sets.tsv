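# Published geometric-mean minimal distances (A) between residues on lid
# helices B, C and D of the DnaK substrate-binding domain in complex with
# the NRLLLTG hepta-peptide, at the 3.5 A report cutoff.  Conditions:
# crystal structure, wild-type simulation (WT), double-charged peptide
# (N1R), uncharged peptide (R2A), lid mutant (K577E).  Transcribed
# reference input for common-contact analysis.
condition	res_i	res_j	distance_A
crystal	531	581	2.23
crystal	535	581	3.42
crystal	536	578	2.06
crystal	536	579	2.25
crystal	536	576	2.68
crystal	536	577	3.20
crystal	539	572	3.39
crystal	539	588	3.49
crystal	540	576	3.52
crystal	543	569	3.35
crystal	546	595	3.25
crystal	546	591	3.42
crystal	547	573	2.22
crystal	550	562	3.14
WT	536	576	3.14
WT	536	579	3.45
WT	538	588	2.65
WT	539	588	3.58
WT	543	569	3.49
WT	546	569	3.27
WT	547	573	3.33
WT	550	562	3.24
WT	553	562	3.09
WT	575	584	3.58
N1R	531	581	3.53
N1R	534	585	2.08
N1R	538	585	2.23
N1R	538	588	2.11
N1R	546	569	3.38
N1R	547	573	3.50
N1R	557	562	3.54
R2A	531	581	3.24
R2A	535	581	3.59
R2A	536	576	2.86
R2A	536	579	3.44
R2A	538	588	3.51
R2A	546	569	3.34
R2A	547	573	3.26
R2A	561	595	1.80
K577E	531	581	3.04
K577E	536	576	2.85
K577E	536	579	3.31
K577E	538	588	3.25
K577E	543	569	3.59
K577E	546	569	3.30
K577E	547	573	3.26
K577E	549	595	2.59
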
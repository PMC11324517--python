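# Transmembrane helix residue ranges for the dopamine transporter in
# full-length numbering.  These ranges are package-maintained conventions
# derived from the transporter's membrane-topology annotation; helix
# boundaries are not sharply defined and users may supply their own file.
helix,chain,start,end
TM1a,A,60,76
TM1b,A,77,90
TM3,A,140,170
TM6a,A,305,318
TM6b,A,319,335
TM8,A,400,430
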
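# Cross-orthologue residue correspondences for core-helix superposition,
# expressed as per-helix constant offsets anchored on conserved motif
# residues (e.g. the TM1 aspartate and the TM3 gate tyrosine).  These are
# package-maintained conventions pending curation from the deposited
# models; rows are expanded to per-residue pairs at load time.
pair,helix,ref_chain,ref_start,ref_end,target_chain,offset
hdat-hsert,TM1b,A,77,90,A,19
hdat-hsert,TM3,A,140,170,A,20
hdat-hsert,TM6a,A,305,318,A,21
hdat-hsert,TM8,A,400,430,A,16
hdat-ddat,TM1b,A,77,90,A,-33
hdat-ddat,TM3,A,140,170,A,-32
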
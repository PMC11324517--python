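# Default ring and moiety definitions for the interaction analyses.
#
# The two ring atom lists are the published stacking definitions: the
# indole ring of W84 and the adenine ring of the allosteric ligand
# (deposited residue name MRS).  The beta-CFT moiety groups follow the
# standard tropane atom-numbering convention and are a package default
# that users should adapt to their topology's ligand atom names.

[rings.w84_indole]
resseq = 84
resname = "TRP"
atoms = ["CG", "CD1", "NE1", "CE2", "CZ2", "CH2", "CZ3", "CE3", "CD2"]

[rings.mrs_adenine]
resname = "MRS"
atoms = ["N3", "C4", "N1", "C3", "C5", "N4", "C6", "N5", "C2"]

[moieties.cft_tropane]
atoms = ["N8", "C1", "C2", "C3", "C4", "C5", "C6", "C7"]

[moieties.cft_fluorophenyl]
atoms = ["C11", "C12", "C13", "C14", "C15", "C16", "F17"]

[moieties.cft_carbomethoxy]
atoms = ["C9", "O1", "O2", "C10"]
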
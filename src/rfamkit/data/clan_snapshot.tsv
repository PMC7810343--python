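# rfamkit bundled clan snapshot (family_accession -> clan_accession).
# Covers the families exercised by the bundled fixtures; refresh from the
# live service with `rfamkit refresh-clans` for a complete, current table.
RF00005	CL00001
RF01852	CL00001
RF03117	CL00116
RF03120	CL00116
RF03121	CL00117
RF03125	CL00117
RF00165	CL00117
RF00164	CL00117
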
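family_id	role
# Curated role assignments documented for the reference CGF catalog:
# spike plug (Cis6), tail fiber (Cis13 / AIg19) families.
CIS_cluster40	Cis6
CIS_cluster80	Cis6
CIS_cluster14	Cis13
CIS_cluster84	AIg19
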
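# Synthetic allowlist of gut-resident genera (user-editable stand-in).
# One genus label per line; lines starting with '#' are ignored.
Bacteroides
Prevotella 9
Faecalibacterium
Blautia
Ruminococcus 2
Roseburia
Alistipes
Akkermansia
Agathobacter
Anaerostipes
Bifidobacterium
Butyricicoccus
Christensenellaceae R-7 group
Collinsella
Coprococcus 2
Dialister
Dorea
Escherichia-Shigella
Eubacterium coprostanoligenes group
Eubacterium eligens group
Eubacterium hallii group
Eubacterium rectale group
Fusicatenibacter
Lachnoclostridium
Lachnospira
Lachnospiraceae NK4A136 group
Odoribacter
Oscillibacter
Parabacteroides
Paraprevotella
Parasutterella
Phascolarctobacterium
Romboutsia
Ruminiclostridium 9
Ruminococcaceae UCG-002
Ruminococcaceae UCG-013
Ruminococcaceae UCG-014
Ruminococcus 1
Streptococcus
Subdoligranulum
Sutterella
Tyzzerella 4
Veillonella
Victivallis
Barnesiella
Butyricimonas
Desulfovibrio
Haemophilus
Holdemanella
Intestinibacter
Megamonas
Megasphaera
Mitsuokella
Slackia
Terrisporobacter
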
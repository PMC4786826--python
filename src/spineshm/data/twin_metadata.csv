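subject_id,pair_id,sex,age,bmi,selfreport_concordance,mri_concordance,status_note,selfreport_note
19,pair01,F,48,29.39,Concordant,Concordant,Normal,Some LBP in past year
20,pair01,F,48,31.23,Concordant,Concordant,Normal,Some LBP in past year
45,pair02,M,47,27.12,Concordant,Concordant,Normal,No history of LBP
46,pair02,M,47,24.82,Concordant,Concordant,Normal,No history of LBP
85,pair03,M,46,28.71,Concordant,Concordant,Normal,No history of LBP
86,pair03,M,46,24.97,Concordant,Concordant,Normal,No history of LBP
125,pair04,F,43,22.13,Concordant,Discordant,Normal,No history of LBP
126,pair04,F,43,23.3,Concordant,Discordant,Hemangioma L4,No history of LBP
189,pair05,M,48,22.13,Concordant,Concordant,Normal,3 days mild LBP in last year
190,pair05,M,48,23.3,Concordant,Concordant,Normal,3 days mild LBP in last year
13,pair06,M,44,20.58,Discordant,Discordant,Normal,No history of LBP
14,pair06,M,44,21.45,Discordant,Discordant,Comp.Fracture L1,Compression fracture 1996
299,pair07,F,48,27.1,Discordant,Discordant,Disc Degeneration L1,Daily LBP with sciatica.
300,pair07,F,48,25.59,Discordant,Discordant,Normal,No history of LBP
353,pair08,M,45,23.55,Discordant,Discordant,Schmorl's Node L2,No history of LBP
354,pair08,M,45,26.3,Discordant,Discordant,Laminectomy L4-5,Daily LBP/Prior disc surgery
391,pair09,M,43,31.46,Discordant,Discordant,Hemilaminectomy L4,No history of LBP
392,pair09,M,43,31.86,Discordant,Discordant,Disc Degeneration L3-4,Prior disc surgery
393,pair10,F,43,26.03,Discordant,Discordant,Normal,Frequent LBP
394,pair10,F,43,26.13,Discordant,Discordant,Disc Prolapse L4-5,No history of LBP
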
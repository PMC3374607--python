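# Concordance lookup mapping lower-rank Firmicutes names (RDP classifier
# output, matched after canonicalization: lower case, punctuation stripped)
# to the three Firmicutes subdivisions used by the seven-category binning.
# Edit freely; unlisted names fall through to Other.
Clostridium IV	Firmicutes_ClostridiumIV
Clostridium Group IV	Firmicutes_ClostridiumIV
Clostridium cluster IV	Firmicutes_ClostridiumIV
Clostridiales Incertae Sedis IV	Firmicutes_ClostridiumIV
Ruminococcaceae	Firmicutes_ClostridiumIV
Faecalibacterium	Firmicutes_ClostridiumIV
Ruminococcus	Firmicutes_ClostridiumIV
Clostridium XIVa	Firmicutes_ClostridiumXIVa
Clostridium Group XIVa	Firmicutes_ClostridiumXIVa
Clostridium cluster XIVa	Firmicutes_ClostridiumXIVa
Lachnospiraceae	Firmicutes_ClostridiumXIVa
Blautia	Firmicutes_ClostridiumXIVa
Roseburia	Firmicutes_ClostridiumXIVa
Coprococcus	Firmicutes_ClostridiumXIVa
Dorea	Firmicutes_ClostridiumXIVa
Bacillus	Firmicutes_Bacillus
Bacilli	Firmicutes_Bacillus
Bacillales	Firmicutes_Bacillus
Lactobacillales	Firmicutes_Bacillus
Lactobacillaceae	Firmicutes_Bacillus
Streptococcaceae	Firmicutes_Bacillus
Streptococcus	Firmicutes_Bacillus
Lactobacillus	Firmicutes_Bacillus
Enterococcaceae	Firmicutes_Bacillus
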
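{
  "registry_pairs_identified": 221,
  "registry_pairs_presumed_concordant": 146,
  "registry_pairs_presumed_discordant": 75,
  "individuals_approached": 442,
  "individuals_responded": 372,
  "responding_complete_pairs_presumed_concordant": 117,
  "responding_complete_pairs_presumed_discordant": 48
}
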
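# Named motif regular expressions used by the regex scanner and, for
# planted architectures, by the synthetic-data generator.
#
# Syntax: upper-case residue = literal, 'x' = any of the 20 amino acids,
# [..] = character class. Widths follow the published descriptions (the LD
# consensus LDxLLxxL; a 22-residue EPLIN motif adjacent to the LIM
# C-terminus; a 12-residue leucine-rich PINCH motif immediately C-terminal
# of LIM E; 15-20 residue glycine-rich CRP motifs after each LIM; TMA1/TMA2
# separated by 17-18 residues N-terminal to the PET domain). Apart from LD,
# whose consensus is established, the residue-level patterns here are
# package defaults standing in for curated ones: motif regexes are data, and
# users analysing real proteomes should supply their own table.
motifs:
  LD: "LDxLLxxL"
  EM: "WxxEELxxLLxxLxxEWxxLLx"
  Gly: "GxGGxGGxGGxxGGG"
  PM: "LxxLLxxLLxxL"
  TMA1: "FxxQLxxELxxW"
  TMA2: "YxxHLxxFLx"
  ZyM: "LExLLxxLxxxK"
  AM: "PxYxxALxxxLxxA"
  ZM: "SLRETxxxTPxE"
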
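# Presence/absence of the 14 LIM classes across the nine sampled species,
# as reported in the published survey's per-class results (partial = the
# half-filled squares: the class is evidenced only by proteins with
# degraded or extended architectures in that species).
#
# Species codes: Co Capsaspora owczarzaki, Sr Salpingoeca rosetta,
# Mb Monosiga brevicollis, Aq Amphimedon queenslandica, Ml Mnemiopsis
# leidyi, Ta Trichoplax adhaerens, Nv Nematostella vectensis,
# Dm Drosophila melanogaster, Hs Homo sapiens. Unlisted species are absent.
rows:
  ABLIM:   {Aq: present, Ml: present, Ta: partial, Nv: present, Dm: present, Hs: present}
  CRP:     {Co: present, Aq: present, Ml: present, Nv: present, Dm: present, Hs: present}
  ENIGMA:  {Aq: present, Ml: present, Ta: present, Nv: present, Dm: present, Hs: present}
  EPLIN:   {Co: present, Sr: partial, Mb: partial, Aq: partial, Ta: present, Nv: present, Dm: present, Hs: present}
  LASP:    {Co: present, Sr: present, Mb: partial, Aq: present, Ml: present, Nv: present, Dm: present, Hs: present}
  LHX:     {Aq: present, Ml: present, Ta: present, Nv: present, Dm: present, Hs: present}
  LIMK:    {Co: partial, Aq: present, Nv: present, Dm: present, Hs: present}
  LMO:     {Ta: present, Nv: present, Dm: present, Hs: present}
  LMO7:    {Aq: present, Ml: present, Nv: present, Dm: partial, Hs: present}
  MICAL:   {Aq: present, Ml: present, Ta: present, Nv: present, Dm: present, Hs: present}
  PXN:     {Co: present, Sr: present, Mb: present, Aq: present, Ml: present, Ta: present, Nv: present, Dm: present, Hs: present}
  PINCH:   {Co: present, Aq: present, Ml: present, Ta: present, Nv: present, Dm: present, Hs: present}
  TES:     {Sr: present, Mb: present, Aq: present, Ml: present, Ta: present, Nv: present, Dm: present, Hs: present}
  ZYX:     {Aq: present, Ml: partial, Nv: present, Dm: present, Hs: present}
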
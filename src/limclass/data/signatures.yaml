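# Declarative class signatures for the 14 LIM classes.
#
# A class holds one or more families. Each family gives the number of LIM
# domains (an integer or [min, max] range), an ordered N-to-C template of
# architectural elements (the string "lim" for a LIM slot, {domain: NAME}
# for a non-LIM profile-model hit, {motif: NAME} for a named motif;
# "required: false" marks elements whose absence is tolerated with a
# partial-architecture flag), optional forbidden elements, and spacing
# constraints (residue coordinates 1-based inclusive; "start" constrains an
# element's start position from the amino terminus, "gap" the unoccupied
# residues between two elements).
#
# required_criteria names the subset of the four classification criteria
# (count, groups, order, architecture) a protein must satisfy to enter the
# class. The published analysis states only that "a reasonable subset" was
# required per class; the subsets below are this package's reconstruction
# (group-anchored for classes whose identity rests on LIM phylogeny,
# architecture-anchored for the rest) and can be tightened or loosened.
#
# Typical widths (residues) for the non-LIM domain models, used by the
# synthetic generator when laying out planted architectures.
domains:
  VHP: 35
  PDZ: 85
  SH3: 55
  Nebulin: 30
  Homeobox: 57
  Pkinase: 120
  CH: 100
  DUF3585: 80
  PET: 90
  FAD_region: 150
  HalfLIM: 25
  RA: 90
  TFIIA: 60
  zf-C2H2: 23

classes:
  ABLIM:
    required_criteria: [count, groups, architecture]
    families:
      Ablim:
        lim_count: 4
        template:
          - lim
          - lim
          - lim
          - lim
          - {domain: VHP, required: false}

  CRP:
    required_criteria: [count, architecture]
    families:
      Crp:
        lim_count: [1, 2]
        template:
          - lim
          - {motif: Gly}
          - {lim: true, required: false}
          - {motif: Gly, required: false}

  ENIGMA:
    required_criteria: [count, architecture]
    families:
      Alp:
        lim_count: 1
        template:
          - {domain: PDZ}
          - {motif: ZM, required: false}
          - {motif: AM, required: false}
          - lim
      Enigma:
        lim_count: 3
        template:
          - {domain: PDZ}
          - {motif: ZM, required: false}
          - {motif: AM, required: false}
          - lim
          - lim
          - lim
      Tungus:
        lim_count: 4
        template:
          - {domain: PDZ}
          - {motif: ZM, required: false}
          - lim
          - lim
          - lim
          - lim

  EPLIN:
    required_criteria: [count, architecture]
    families:
      Eplin:
        lim_count: 1
        template:
          - lim
          - {motif: EM}
        spacing:
          - {a: "lim:1", b: "motif:EM:1", measure: gap, min: 0, max: 5}

  LASP:
    required_criteria: [count, architecture]
    families:
      Lasp:
        lim_count: 1
        template:
          - lim
          - {domain: Nebulin}
          - {domain: Nebulin}
          - {domain: SH3, required: false}
        spacing:
          - {element: "lim:1", measure: start, min: 5, max: 6}
          - {element: "domain:Nebulin:1", measure: start, min: 67, max: 67}
          - {element: "domain:Nebulin:2", measure: start, min: 99, max: 105}

  LHX:
    required_criteria: [count, architecture]
    families:
      Lhx:
        lim_count: 2
        template:
          - lim
          - lim
          - {domain: Homeobox}

  LMO:
    required_criteria: [count, architecture]
    families:
      Lmo:
        lim_count: 2
        template:
          - lim
          - lim
        forbidden:
          - {domain: Homeobox}
          - {domain: PDZ}

  LIMK:
    required_criteria: [count, architecture]
    families:
      Limk:
        lim_count: 2
        template:
          - lim
          - lim
          - {domain: PDZ}
          - {domain: Pkinase}

  LMO7:
    required_criteria: [count, architecture]
    families:
      Lmo7:
        lim_count: 1
        template:
          - {domain: CH}
          - {domain: PDZ, required: false}
          - lim
        forbidden:
          - {domain: DUF3585}
          - {motif: EM}

  MICAL:
    required_criteria: [count, architecture]
    families:
      Mical:
        lim_count: 1
        template:
          - {domain: FAD_region}
          - {domain: CH}
          - lim
          - {domain: DUF3585}
      Mical-like:
        lim_count: 1
        template:
          - {domain: CH}
          - lim
          - {domain: DUF3585}

  PXN:
    required_criteria: [count, groups, architecture]
    families:
      Pxn:
        lim_count: 4
        template:
          - {motif: LD}
          - lim
          - lim
          - lim
          - lim

  PINCH:
    required_criteria: [count, groups, architecture]
    families:
      Pinch:
        lim_count: 5
        template:
          - lim
          - lim
          - lim
          - lim
          - lim
          - {motif: PM}
        spacing:
          - {a: "lim:5", b: "motif:PM:1", measure: gap, min: 0, max: 2}

  TES:
    required_criteria: [count, architecture]
    families:
      Tes:
        lim_count: [2, 3]
        template:
          - {motif: TMA1, required: false}
          - {motif: TMA2, required: false}
          - {domain: PET}
          - lim
          - lim
          - {lim: true, required: false}
        spacing:
          - {a: "motif:TMA1:1", b: "motif:TMA2:1", measure: gap, min: 17, max: 18}
      Etes:
        lim_count: 6
        template:
          - {motif: TMA1, required: false}
          - {motif: TMA2, required: false}
          - {domain: PET}
          - lim
          - lim
          - lim
          - lim
          - lim
          - lim
        spacing:
          - {a: "motif:TMA1:1", b: "motif:TMA2:1", measure: gap, min: 17, max: 18}
      Fhl:
        lim_count: 4
        template:
          - {domain: HalfLIM}
          - lim
          - lim
          - lim
          - lim
        forbidden:
          - {domain: PET}

  ZYX:
    required_criteria: [count, architecture]
    families:
      Zyx:
        lim_count: 3
        template:
          - {motif: ZyM, required: false}
          - lim
          - lim
          - lim
        spacing:
          - {a: "lim:1", b: "lim:2", measure: gap, min: 0, max: 15}
          - {a: "lim:2", b: "lim:3", measure: gap, min: 0, max: 15}
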
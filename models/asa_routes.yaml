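# Route grouping for the regulation of the aspartate-semialdehyde (ASA)
# supply block by ASA, in the aspartate-derived amino acid synthesis model.
#
# Reaction numbering convention: 1/2 = Thr-inhibited aspartate kinases
# (AKI, AKII), 3/4 = Lys-inhibited aspartate kinases (AK2, AK1),
# 5 = ASA dehydrogenase (supply-adjacent), 6/7 = homoserine dehydrogenase
# isoenzymes (Thr branch), 9 = threonine synthase (Thr supply-adjacent),
# 14/15 = dihydrodipicolinate synthase isoenzymes (Lys branch).
# Adjust the ids below to the identifiers used in the SBML file.
mediators:
  Thr:
    species: Thr
    block: R9
  Lys:
    species: Lys
    blocks: [R14, R15]
routes:
  - name: direct_via_R5
    stage1: [R5]
  - name: via_Thr_R1
    stage1: [R6, R7]
    mediator: Thr
    numerator: [R1]
    denominator: [R1, R2]
  - name: via_Thr_R2
    stage1: [R6, R7]
    mediator: Thr
    numerator: [R2]
    denominator: [R1, R2]
  - name: via_Lys_R3
    stage1: [R14, R15]
    mediator: Lys
    numerator: [R3]
    denominator: [R3, R4]
  - name: via_Lys_R4
    stage1: [R14, R15]
    mediator: Lys
    numerator: [R4]
    denominator: [R3, R4]
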
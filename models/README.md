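# Case-study models

The two published kinetic models analysed in the documentation are not
redistributed with this package. To run the case-study reproduction
(`tests/test_acceptance.py` case-study tests, and the corresponding CLI
workflows), download them from the BioModels database and place them here:

- `BIOMD0000000017.xml` — pyruvate-branch metabolism of *Lactococcus
  lactis* (Hoefnagel et al.), with the ATP/ADP, NADH/NAD+ and
  acetyl-CoA/CoA moiety-conserved cycles.
- `BIOMD0000000212.xml` — aspartate-derived amino acid synthesis in
  *Arabidopsis thaliana* (Curien et al.), with four aspartate-kinase
  isoenzymes inhibited by threonine and lysine.

Download URLs follow the pattern
`https://www.ebi.ac.uk/biomodels/BIOMD0000000017`.

`asa_routes.yaml` is a route-grouping template for decomposing the
regulation of the aspartate-semialdehyde supply block; edit the reaction
identifiers to match the ones used in the SBML file you download.
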
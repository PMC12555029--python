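default_label: unassigned
nodes:
- when:
    DNA1: '-'
    DNA2: '-'
  label: non_cell
- when:
    CD31: +
  label: endothelial
- when:
    CD45: +
  children:
  - when:
      CD68: +
      CD163: +
    label: M2_macrophage
  - when:
      CD68: +
    label: M0_macrophage
  - when:
      CD4: +
      FOXP3: +
    label: Treg
  - when:
      CD8a: +
    label: CD8_T
  - when:
      CD4: +
    label: CD4_T
  - when:
      CD66b: +
      CD11b: +
    label: neutrophil
  - when:
      CD20: +
      CD11b: +
    label: memory_B
  - when:
      CD20: +
    label: B_cell
  - when:
      CD123: +
    label: DC
  - when:
      CD56: +
    label: NK
  - when:
      CD33: +
    label: myeloid
  - when: {}
    label: undefined_CD45
- when:
    FOXL2: +
  children:
  - when:
      COL1A1: +
    label: FOXL2+COL1A1+
  - when: {}
    label: FOXL2+COL1A1-
- when:
    COL1A1: +
    aSMA: +
  label: COL1A1+aSMA+
- when:
    COL1A1: +
  label: COL1A1+
- when:
    aSMA: +
  label: aSMA+
- when:
    Vimentin: +
  label: other_stromal
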
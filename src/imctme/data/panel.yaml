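markers:
- name: FOXL2
  metal: Eu153
  category: tumor
  phenotypic: true
- name: SF1
  metal: Nd143
  category: tumor
  phenotypic: true
- name: Calretinin
  metal: Nd145
  category: tumor
  phenotypic: true
- name: InhibinA
  metal: Nd146
  category: tumor
  phenotypic: true
- name: ERa
  metal: Gd158
  category: tumor
  phenotypic: true
- name: PR
  metal: Gd160
  category: tumor
  phenotypic: true
- name: COL1A1
  metal: Tm169
  category: stromal
  phenotypic: true
- name: aSMA
  metal: Pr141
  category: stromal
  phenotypic: true
- name: Vimentin
  metal: Nd144
  category: stromal
  phenotypic: true
- name: S100A4
  metal: Sm147
  category: stromal
  phenotypic: true
- name: PDGFRa
  metal: Sm149
  category: stromal
  phenotypic: true
- name: PDGFRb
  metal: Nd150
  category: stromal
  phenotypic: true
- name: FAP
  metal: Eu151
  category: stromal
  phenotypic: true
- name: CD45
  metal: Sm152
  category: immune
  phenotypic: true
- name: CD45RO
  metal: Nd148
  category: immune
  phenotypic: true
- name: CD20
  metal: Dy161
  category: immune
  phenotypic: true
- name: CD8a
  metal: Dy162
  category: immune
  phenotypic: true
- name: CD4
  metal: Gd156
  category: immune
  phenotypic: true
- name: FOXP3
  metal: Dy163
  category: immune
  phenotypic: true
- name: CD25
  metal: Dy164
  category: immune
  phenotypic: true
- name: CD56
  metal: Ho165
  category: immune
  phenotypic: true
- name: CD33
  metal: Er166
  category: immune
  phenotypic: true
- name: CD11b
  metal: Er167
  category: immune
  phenotypic: true
- name: CD68
  metal: Er168
  category: immune
  phenotypic: true
- name: CD163
  metal: Yb171
  category: immune
  phenotypic: true
- name: CD66b
  metal: Yb172
  category: immune
  phenotypic: true
- name: CD123
  metal: Yb173
  category: immune
  phenotypic: true
- name: GranzymeB
  metal: Yb174
  category: immune
  phenotypic: true
- name: CD31
  metal: Sm154
  category: endothelial
  phenotypic: true
- name: Ki67
  metal: Lu175
  category: functional
  phenotypic: false
- name: ADAMTS1
  metal: Yb176
  category: functional
  phenotypic: false
- name: ADAMTS5
  metal: Gd155
  category: functional
  phenotypic: false
- name: DNA1
  metal: Ir191
  category: DNA
  phenotypic: false
- name: DNA2
  metal: Ir193
  category: DNA
  phenotypic: false
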
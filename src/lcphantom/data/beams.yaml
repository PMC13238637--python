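# Default beam qualities: Cu-hardened fluoroscopic beams Q1-Q3.
beams:
  - name: Q1
    kvp: 65
    added_cu_mm: 0.3
    inherent_al_mm: 3.0
    fdd_mm: 1000
  - name: Q2
    kvp: 80
    added_cu_mm: 0.6
    inherent_al_mm: 3.0
    fdd_mm: 1000
  - name: Q3
    kvp: 100
    added_cu_mm: 0.9
    inherent_al_mm: 3.0
    fdd_mm: 1000
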
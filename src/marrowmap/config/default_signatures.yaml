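# Default gene signatures shipped with marrowmap.
#
# These lists are PACKAGE DEFAULTS matched to the synthetic reference
# panel (marrowmap.simulate.default_reference_profiles): the signature
# names follow the field's conventions (a 12-gene chemokine signature,
# an 8-gene follicular-helper-T signature, a 29-gene TLS-imprint
# signature, and an M2/M1 macrophage-polarization ratio pair), but the
# gene memberships are package choices, not authoritative published
# lists.  Replace with your own lists for real data.
signatures:
  - name: 12chem
    kind: single_set
    genes: [CCL2, CCL3, CCL4, CCL5, CCL8, CCL18, CCL19, CCL21,
            CXCL9, CXCL10, CXCL11, CXCL13]
  - name: Tfh
    kind: single_set
    genes: [CXCL13, ICOS, PDCD1, SH2D1A, TIGIT, CD200, BTLA, IL21]
  - name: TLS_imprint
    kind: single_set
    genes: [CD3D, CD3E, CD2, TRAC, IL7R, CCR7, SELL, CD8A, GZMK, CCL5,
            MS4A1, CD79A, CD79B, CD19, CXCL13, CCL19, CCL21, IGHG1,
            JCHAIN, MZB1, CD38, ICOS, PDCD1, SH2D1A, TIGIT, LTB, LAMP3,
            CD40LG, NKG7]
  - name: M2_predominance
    kind: ratio_pair
    set_up: [CD163, MRC1, MSR1, STAB1, CCL18, CCL22]
    set_down: [IL1B, TNF, CD80, SOCS1, CXCL9, CXCL10]
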
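# Default CUIs treated as statistical-significance concepts
# (significance, P value, z-score).  Editable: curation teams should
# extend this list from the UTS Metathesaurus browser for their domain.
C0237881  # Statistical Significance
C1709380  # P value
C2347025  # z-score
C0392762  # statistically significant
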
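# Static, configurable therapeutic annotations per MAP.  Descriptive only;
# not medical advice and not an evidence-tiering engine.
MAP1.1:
  - "KRAS mutant: not eligible for anti-EGFR therapy."
  - ">=3 pathogenic mutations typical: single-target therapy prone to primary resistance; consider multitarget combinations against the druggable lesions detected."
  - "Higher mutation burden than MAP2.2/4.2 may support exploring immune-checkpoint inhibition."
MAP1.2:
  - "KRAS mutant: not eligible for anti-EGFR therapy."
  - "No targetable lesion beyond KRAS/TP53; standard chemotherapy plus anti-VEGF; MEK inhibition a possible exception."
  - "Mutant-TP53 reactivation approaches a future option."
MAP2.1:
  - "KRAS mutant: not eligible for anti-EGFR therapy."
  - "Highest frequency of PI3K-AKT pathway activation (PIK3CA/AKT1/PTEN) in a TP53 wild-type background; PI3K-axis targeting and TP53-reactivation strategies of interest."
MAP2.2:
  - "KRAS mutant: not eligible for anti-EGFR therapy."
  - "Single-mutation tumor; immunotherapy counterintuitive given the low mutation load."
MAP3.1:
  - "Anti-EGFR monotherapy likely ineffective: frequent PIK3CA/NRAS/BRAF/SMAD4 primary-resistance mutations; plan combinations."
  - "Contains MSI-high cases: immune-reactivation therapy opportunities."
MAP3.2:
  - "TP53-only tumor, quadruple-negative-like: most eligible for chemotherapy plus anti-EGFR (no known predictable resistance mechanism)."
MAP4.1:
  - "Highest BRAF V600E frequency: consider combined BRAF/EGFR (+/- MEK) targeting; avoid anti-EGFR alone (PIK3CA/NRAS/BRAF/FBXW7 resistance mutations frequent)."
  - "Majority of MSI-high cases cluster here: strongest candidates for immune-checkpoint inhibitors."
MAP4.2:
  - "Mutation-free on the panel, quadruple-negative-like: most eligible for chemotherapy plus anti-EGFR."
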
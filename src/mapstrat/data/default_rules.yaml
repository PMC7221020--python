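# Default clinical-relevance curation rules for the 22-gene panel.
# Quality floor first; then per-gene rules.  A core-gene record failing its
# rule with a non-benign label is a VUS and disqualifies the whole sample.
quality_threshold: 30
core_genes: [KRAS, BRAF, PIK3CA, TP53]
genes:
  KRAS:
    codon_whitelist: [12, 13, 59, 61, 117, 146]
  BRAF:
    exact_variant_whitelist: ["p.V600E"]
  PIK3CA:
    # Hotspot exons in the numbering of the panel's reference transcript
    # (NM_006218); other transcript schemes call these exons 9/20.
    exon_whitelist: [10, 21]
  TP53:
    accepted_labels: [pathogenic, likely_pathogenic]
    # Offline stand-in for "ClinVar pathogenic and/or hotspot": the most
    # recurrent DNA-binding-domain hotspot codons.
    hotspot_codons: [175, 176, 179, 196, 213, 220, 245, 248, 249, 273, 282]
  NRAS: &label_rule
    accepted_labels: [pathogenic, likely_pathogenic, predicted_deleterious]
  FBXW7: *label_rule
  SMAD4: *label_rule
  PTEN: *label_rule
  MET: *label_rule
  STK11: *label_rule
  EGFR: *label_rule
  CTNNB1: *label_rule
  AKT1: *label_rule
  ERBB2: *label_rule
  ERBB4: *label_rule
  FGFR1: *label_rule
  ALK: *label_rule
  MAP2K1: *label_rule
  NOTCH1: *label_rule
  DDR2: *label_rule
  FGFR3: *label_rule
  FGFR2: *label_rule
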
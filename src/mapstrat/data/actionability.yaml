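# Actionability lookup: genes whose retained mutations carry a
# clinical-evidence-based therapeutic implication (OncoKB-style tiering),
# with the druggable subset flagged.  Pure configuration data.
criteria:
  KRAS: any
  NRAS: any
  BRAF: any
  PIK3CA: any
  EGFR: any
  MET: any
  PTEN: any
  AKT1: any
  ERBB2: any
  ALK: any
  MAP2K1: any
druggable: [BRAF, PIK3CA, EGFR, MET, ERBB2, ALK, AKT1]
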
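{
  "pairs": [
    ["CTSS", "ADM"],
    ["HLA-DPA1", "IFITM1"],
    ["HSPA2", "NR2F1"],
    ["MICB", "CX3CR1"],
    ["RBP4", "TNFRSF19"],
    ["NOX4", "TNFSF13B"],
    ["CHIT1", "CCL4"],
    ["VEGFA", "AR"],
    ["VEGFA", "ITGB2"],
    ["ITGAV", "TNFSF13"],
    ["WNT5A", "NR2F1"],
    ["BTK", "TNFSF13B"],
    ["IFITM1", "TNFSF13"],
    ["TNFSF13B", "CSF3R"]
  ],
  "coefficients": [
    -0.13784168,
    -0.536023127,
    -0.813388891,
    0.547230703,
    -0.479900288,
    -0.536067102,
    -0.055801169,
    0.295949021,
    0.313650746,
    0.033017443,
    -0.421788958,
    -0.212282282,
    0.012878529,
    0.448335019
  ],
  "cutoff": 0.184,
  "meta": {
    "name": "IRGPI-14 papillary renal cell carcinoma signature",
    "disease": "papillary renal cell carcinoma (PRCC)",
    "endpoint": "overall survival",
    "discovery_cohort": {"source": "TCGA-KIRP RNA-seq (FPKM)", "n_samples": 287},
    "validation_cohort": {"source": "GEO GSE2748 microarray", "n_samples": 28},
    "cutoff_rule": "time-dependent ROC at 1 year, point closest to (FPR 0, TPR 1)",
    "immune_gene_source": "ImmPort immune-related gene list (2498 genes)"
  }
}
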
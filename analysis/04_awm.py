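"""Association weight matrix: z-score, key-trait/3-trait selection, gene
assignment, 1-Mb dedup, and trait clustering."""
from common import run_through

a = run_through("awm")["awm"]
print(f"AWM: {a['snps_selected']} SNPs selected -> {a['awm_rows']} rows "
      f"({a['gene_rows']} genes, {a['mirna_rows']} miRNAs, {a['desert_rows']} desert nodes); "
      f"k=2 trait clusters of sizes {a['trait_cluster_sizes']} "
      f"(fatness vs growth/conformation)")
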
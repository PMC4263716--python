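"""Mixed-model single-SNP association for the 12 traits (pedigree polygenic control)."""
from common import run_through

g = run_through("gwas")["gwas"]
print(f"GWAS: {g['snps_tested']} SNPs x {g['traits']} traits over "
      f"{g['individuals']} phenotyped animals ({g['monomorphic']} monomorphic flagged); "
      f"per-trait tables under results/pipeline/gwas/")
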
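"""Genotype quality control: missingness, MAF < 5%, unmapped SNPs, Mendelian checks."""
from common import run_through

qc = run_through("qc")["qc"]
print(f"QC: {qc['snps_input']} SNPs in; removed {qc['snps_removed_maf']} for MAF, "
      f"{qc['snps_removed_unmapped']} unmapped; "
      f"{qc['individuals_removed_missingness']} animals dropped; "
      f"{qc['mendelian_errors']} Mendelian errors; retained {qc['snps_retained']} SNPs "
      f"x {qc['individuals_retained']} animals")
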
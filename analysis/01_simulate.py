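"""Simulate the three-generation Iberian x Landrace backcross stand-in.

Writes PED/MAP genotypes, pedigree, 12-trait phenotypes, gene/miRNA
annotation, regulator lists and the planted truth under results/pipeline/sim.
"""
from common import run_through

st = run_through("simulate")["simulate"]
print(f"simulated {st['individuals']} animals ({st['phenotyped']} phenotyped), "
      f"{st['snps']} SNPs, {st['genes']} genes, {st['mirnas']} miRNAs, "
      f"{st['qtls']} planted antagonistic QTLs")
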
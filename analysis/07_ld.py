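"""Linkage disequilibrium (D', r^2) around the top trio member's SNP."""
from common import run_through

l = run_through("ld")["ld"]
print(f"LD window around {l['center_snp']}: {l['pairs']} pairs; "
      f"max D' = {l.get('max_d_prime')}, median D' = {l.get('median_d_prime')}")
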
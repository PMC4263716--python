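"""Best regulator trio: maximal neighbor coverage, minimal redundancy."""
from common import run_through

t = run_through("trio")["trio"]
print(f"trio: {t['members']} cover {t['coverage']} genes "
      f"(redundancy {t['redundancy']}, degrees {t['member_degrees']}); "
      f"subnetwork {t['subnetwork_edges']} edges / {t['subnetwork_nodes']} nodes "
      f"out of {t['n_regulators_in_network']} regulators")
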
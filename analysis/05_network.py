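"""PCIT co-association network and the |r| > 0.86 strong-edge reduction."""
from common import run_through

n = run_through("network")["network"]
print(f"network: PCIT kept {n['edges_pcit']} edges over {n['awm_rows_used']} rows; "
      f"|r| > {n['edge_threshold']} leaves {n['edges_thresholded']} edges / "
      f"{n['nodes_thresholded']} genes; mean degree {n['mean_degree']}, "
      f"mean distance {n['mean_distance']}")
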
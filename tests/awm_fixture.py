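"""Hand-built 20-SNP fixture for the AWM selection/assignment/dedup rules.

Every expected row below was enumerated by hand from the rules:
  select:  p(key) < 0.05  OR  >= 3 traits with p < 0.05
  assign:  gene if nearest gene < 2.5 kb; else miRNA if < 10 kb; else
           standalone node if nearest gene > 1,000 kb; else discard
  dedupe:  1-Mb single-linkage clusters keep the most-associated SNP
"""

import numpy as np
import pandas as pd

TRAITS4 = ["K", "T2", "T3", "T4"]  # K is the key phenotype


def build_fixture():
    snp_map = pd.DataFrame([
        # chrom, snp_id, cm, bp
        (1, "S01", 0.012, 12_000),      # inside gene GA           -> GA
        (1, "S02", 0.021, 21_000),      # 1 kb past GA             -> GA (cluster with S01)
        (1, "S03", 2.995, 2_995_000),   # 5 kb before GB           -> discarded (intermediate)
        (1, "S04", 3.001, 3_001_000),   # inside GB                -> GB
        (1, "S05", 5.008, 5_008_000),   # 7.9 kb past miRNA M1     -> M1
        (1, "S06", 20.0, 20_000_000),   # >1 Mb from any gene      -> desert node S06
        (1, "S07", 20.5, 20_500_000),   # desert, clusters with S06
        (1, "S08", 50.005, 50_005_000), # inside GC but only 2 assoc traits -> not selected
        (1, "S09", 50.006, 50_006_000), # inside GC                -> GC
        (1, "S10", 60.0, 60_000_000),   # nothing significant      -> not selected
        (2, "S11", 1.0005, 1_000_500),  # inside GD                -> GD
        (2, "S12", 1.9, 1_900_000),     # 880 kb from GD           -> discarded (intermediate)
        (2, "S13", 3.2, 3_200_000),     # >1 Mb from GD            -> desert node S13
        (3, "S14", 1.0, 1_000_000),     # chrom without features; never selected
        (3, "S15", 2.0, 2_000_000),
        (3, "S16", 3.0, 3_000_000),
        (3, "S17", 4.0, 4_000_000),
        (3, "S18", 5.0, 5_000_000),
        (3, "S19", 6.0, 6_000_000),
        (3, "S20", 7.0, 7_000_000),
    ], columns=["chrom", "snp_id", "cm", "bp"])

    annotation = pd.DataFrame([
        (1, 10_000, 20_000, "GA", "gene"),
        (1, 3_000_000, 3_010_000, "GB", "gene"),
        (1, 5_000_000, 5_000_100, "M1", "miRNA"),
        (1, 50_000_000, 50_010_000, "GC", "gene"),
        (2, 1_000_000, 1_020_000, "GD", "gene"),
    ], columns=["chrom", "start", "end", "id", "kind"])

    ns = 0.5  # non-significant
    sg = 0.01
    p = pd.DataFrame({
        "S01": [sg, ns, ns, ns],   # key only                    -> n=1
        "S02": [0.2, sg, sg, sg],  # 3 non-key traits            -> n=3
        "S03": [sg, ns, ns, ns],
        "S04": [0.04, ns, ns, ns],
        "S05": [ns, 0.02, 0.02, 0.02],
        "S06": [0.04, ns, ns, ns],
        "S07": [sg, sg, sg, sg],   # n=4, wins its desert cluster
        "S08": [0.2, sg, sg, ns],  # only 2 traits -> dropped
        "S09": [ns, 0.03, 0.03, 0.03],
        "S10": [ns, ns, ns, ns],
        "S11": [0.03, ns, ns, ns],
        "S12": [ns, sg, sg, sg],
        "S13": [0.02, ns, ns, ns],
        "S14": [ns, ns, ns, ns], "S15": [ns, ns, ns, ns], "S16": [ns, ns, ns, ns],
        "S17": [ns, ns, ns, ns], "S18": [ns, ns, ns, ns], "S19": [ns, ns, ns, ns],
        "S20": [ns, ns, ns, ns],
    }, index=TRAITS4).T
    p.index.name = "snp_id"

    rng = np.random.default_rng(99)
    effects = pd.DataFrame(rng.normal(size=(20, 4)), index=p.index, columns=TRAITS4)

    # hand enumeration of the final AWM rows: feature_id -> representative SNP
    expected = {
        "GA": "S02",   # S02 beats S01 (3 traits vs 1) within the 9-kb cluster
        "GB": "S04",
        "M1": "S05",
        "S07": "S07",  # desert; beats S06 (4 traits vs 1) within 500 kb
        "GC": "S09",
        "GD": "S11",
        "S13": "S13",
    }
    selected_ids = {"S01", "S02", "S03", "S04", "S05", "S06", "S07", "S09",
                    "S11", "S12", "S13"}
    return snp_map, annotation, p, effects, expected, selected_ids
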
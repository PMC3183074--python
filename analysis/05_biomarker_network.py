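"""Partial-correlation network over biomarker slopes and lifespan: the
PC-algorithm skeleton per simulated dataset and the cross-dataset consensus
(solid = always recovered, dashed = sometimes).
"""

import warnings

import pandas as pd

from wormspan import network as net
from wormspan import stats as ws
from wormspan import synthetic as syn

warnings.simplefilter("ignore", syn.TruncationWarning)

networks = []
for trial in range(3):
    cfg = syn.paper_like_config(n_animals=250, seed=50 + trial)
    animals, courses = syn.generate_cohort(cfg)
    df = ws.summary_table(animals, courses)
    data = df[[c for c in df.columns if c.endswith("_slope")]].copy()
    data.columns = [c.replace("_slope", "") for c in data.columns]
    data["lifespan"] = df["lifespan_days"]
    sk = net.pc_skeleton(data, alpha=0.001)
    networks.append(sk)
    print(f"trial {trial}: edges = {sk.edge_list()}")

cons = net.consensus(networks)
print("\nconsensus network:")
print(cons.edge_table().to_string(index=False))
if cons.unplaceable:
    print(f"unplaceable nodes (no edge in any trial): {cons.unplaceable}")
cons.edge_table().to_csv("results/analysis/network_consensus.csv",
                         index=False)
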
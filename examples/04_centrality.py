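"""Expected influence and bridge expected influence of each symptom.

EI is the signed sum of a node's edge weights (its cumulative activating
influence); BEI restricts the sum to edges into the other community and
flags symptoms likely to transmit activation between the two disorders.
"""

import symnet as sn

table = sn.simulate_study(n=1685, seed=1)
items = sn.filter_eligible(table).table[list(sn.NODE_NAMES)]
model = sn.select_network(items)

cent = sn.centrality_table(model)
print("top-5 central symptoms by EI (raw values):")
print(cent.nlargest(5, "EI")[["node", "community", "EI", "strength"]]
      .to_string(index=False, float_format="%.3f"))

print("\ntop-3 bridge symptoms by BEI (raw values):")
print(cent.nlargest(3, "BEI")[["node", "community", "BEI"]]
      .to_string(index=False, float_format="%.3f"))

print("\nHigh-EI nodes are candidate intervention targets for the whole "
      "network; high-BEI nodes are candidate targets for preventing "
      "depression-anxiety comorbidity.")
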
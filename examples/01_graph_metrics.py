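"""Build a binary connectome graph and compute nodal metrics.

A synthetic correlation matrix stands in for a subject's wavelet
correlation matrix; it is thresholded to a connected fixed-density graph
(maximum-|r| spanning tree plus strongest remaining edges) and summarized
node by node.
"""

import numpy as np

from connmap import (
    CorrelationMatrix,
    binarize_connectome,
    clustering,
    degree,
    global_efficiency,
)

rng = np.random.default_rng(0)
n = 30
a = rng.uniform(-1, 1, (n, n))
r = (a + a.T) / 2
np.fill_diagonal(r, 1.0)
corr = CorrelationMatrix(r, [f"region{i + 1}" for i in range(n)])

graph = binarize_connectome(corr, density=0.15)
print(f"graph: {graph.n_nodes} nodes, {graph.n_edges} edges, "
      f"connected={graph.is_connected()}")

d = degree(graph)
e = global_efficiency(graph)
c = clustering(graph)
print(f"degree        min/max = {d.min():.0f}/{d.max():.0f}")
print(f"global eff.   min/max = {e.min():.3f}/{e.max():.3f}")
print(f"clustering    min/max = {c.min():.3f}/{c.max():.3f}")

# High-degree, high-efficiency nodes are the hubs of this connectome;
# every subject graph built at the same density has the same edge count,
# so these nodal values are directly comparable across subjects.
hubs = np.argsort(d)[-3:][::-1]
print("top hubs:", [graph.node_ids[i] for i in hubs])
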
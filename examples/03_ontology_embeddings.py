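"""Random-walk-with-restart node embeddings for a drug ontology.

The ontology graph is diffused with RWR (restart probability 0.5); the
stationary visiting distributions are factorized by SVD, and each node keeps
its coordinates along the top singular directions scaled by the singular
values.  Nearby ontology classes end up with similar embeddings.
"""

import networkx as nx
import numpy as np

from pairview import ontology_embeddings, rwr_node_profiles

# a small two-branch classification tree
edges = [("root", "antineoplastic"), ("root", "cardiovascular"),
         ("antineoplastic", "kinase_inhibitor"), ("antineoplastic", "taxane"),
         ("cardiovascular", "beta_blocker"), ("cardiovascular", "statin")]
graph = nx.Graph(edges)

nodes, profiles = rwr_node_profiles(graph, alpha=0.5)
print("profiles are probability vectors:",
      bool(np.allclose(profiles.sum(axis=1), 1.0)))

table = ontology_embeddings(graph, alpha=0.5, dim=4)
def dist(a, b):
    return float(np.linalg.norm(table.vector(a) - table.vector(b)))

print(f"kinase_inhibitor - taxane       : {dist('kinase_inhibitor', 'taxane'):.4f}")
print(f"kinase_inhibitor - beta_blocker : {dist('kinase_inhibitor', 'beta_blocker'):.4f}")
# siblings under the same parent are closer than nodes across branches
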
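"""Generate a synthetic graph and grow LSMI patches on it.

Builds a zero-truncated Poisson(2) graph of order 2000 with the pairing model
plus rewiring, grows 3-wave patches around 30 random seeds, and prints the
patch inventory: how many non-seed degree records each wave contributes.
The seed degrees alone estimate the mean degree without bias; the non-seed
records are size-biased towards hubs (they are reached along edges), which is
why the bootstrap later resamples them with weights proportional to 1/degree.
"""

import numpy as np

import patchboot as pb

rng = np.random.default_rng(7)
model = pb.ztp(2)
graph = pb.generate_graph(model, 2000, rng)
print(f"graph: {graph.n} vertices, {graph.num_edges} edges, "
      f"mean degree {graph.degrees.mean():.3f} (model mean {model.mean():.3f})")

seeds = pb.sample_seeds(graph, 30, rng)
patchset = pb.lsmi(graph, seeds, 3)

print(f"seed degrees: mean {patchset.seed_degrees().mean():.3f}")
for w in (1, 2, 3):
    view = pb.subpatch(patchset, 30, w)
    records = view.nonseed_degrees()
    print(f"waves ≤ {w}: {records.size:4d} non-seed records, "
          f"raw mean degree {records.mean():.3f} (size-biased upwards)")
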
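"""Detect planted local anomalies in a two-ring motif graph set.

Generates 120 normal two-ring graphs plus 24 graphs in which one node's
links were rewired (destroying the four-ring pattern), trains the detector
on normal graphs only, and reports how well the representation-error score
ranks the anomalies.  A held-out AUC near 1 means anomalous graphs almost
always receive bigger errors than unseen normal graphs.
"""

import numpy as np

from gladc import MotifSpec, SyntheticConfig, TrainConfig, generate_motif_set
from gladc.pipeline import run_holdout_experiment

dataset = generate_motif_set(
    MotifSpec(small_ring=3, large_ring=4, bridge_edges=1),
    SyntheticConfig(n_normal=120, n_anomalous=24, anomaly_type="local",
                    jitter=0.1, seed=7),
)
print(f"{len(dataset)} graphs, feature dim {dataset.feature_dim} "
      f"(degree one-hots), up to {dataset.max_nodes} nodes")

config = TrainConfig(epochs=30, batch_size=32, seed=7)
report = run_holdout_experiment(dataset, config, k=5)

scores = np.array([s for _, _, s in report.records])
labels = np.array([l for _, l, _ in report.records])
print(f"held-out normal graphs:    mean score {scores[labels == 0].mean():.4f}")
print(f"held-out anomalous graphs: mean score {scores[labels == 1].mean():.4f}")
print(f"held-out AUC: {report.auc:.3f}")
print("(AUC = probability a random anomaly outscores a random normal graph)")
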
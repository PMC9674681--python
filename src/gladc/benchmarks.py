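"""Standard seeded planted-anomaly benchmarks for the detector.

These fix the study conditions used throughout the package's evaluation:

* **Motif benchmark** — 400 normal two-ring motif graphs (10% carrying one
  benign extra chord) plus 80 local anomalies; train on the normal graphs
  outside one stratified fold, score that fold.
* **ER contrast benchmark** — 200 normal Erdős–Rényi graphs at p = 0.15 and
  40 anomalous ones at p = 0.6 on 20 nodes, scalar degree features.
* **ER null control** — the same generator with p_anomalous = p_normal, so
  labels carry no signal and cross-validated AUC should sit near 0.5.

All runs use the reference hyperparameters with the training length scaled
to 50 epochs and minibatches of 64 graphs — ample for these graph sizes.
"""

from __future__ import annotations

from .data_io import GraphDataset
from .pipeline import ScoreReport, TrainConfig, run_cv_experiment, run_holdout_experiment
from .synthetic import MotifSpec, SyntheticConfig, generate_er_contrast_set, generate_motif_set

__all__ = [
    "benchmark_config",
    "motif_dataset",
    "er_dataset",
    "motif_benchmark",
    "er_benchmark",
    "null_benchmark",
]

MOTIF_N_NORMAL = 400
MOTIF_N_ANOMALOUS = 80
MOTIF_JITTER = 0.1
ER_N_NORMAL = 200
ER_N_ANOMALOUS = 40
ER_N_NODES = 20
ER_P_NORMAL = 0.15
ER_P_ANOMALOUS = 0.6
EPOCHS = 50
BATCH_SIZE = 64


def benchmark_config(seed: int, ablation: frozenset = frozenset()) -> TrainConfig:
    return TrainConfig(epochs=EPOCHS, batch_size=BATCH_SIZE, seed=seed,
                       ablation=ablation)


def motif_dataset(seed: int, anomaly_type: str = "local") -> GraphDataset:
    return generate_motif_set(MotifSpec(), SyntheticConfig(
        n_normal=MOTIF_N_NORMAL, n_anomalous=MOTIF_N_ANOMALOUS,
        anomaly_type=anomaly_type, jitter=MOTIF_JITTER, seed=seed))


def er_dataset(seed: int, p_anomalous: float = ER_P_ANOMALOUS) -> GraphDataset:
    return generate_er_contrast_set(ER_N_NORMAL, ER_N_ANOMALOUS, ER_N_NODES,
                                    ER_P_NORMAL, p_anomalous, seed)


def motif_benchmark(seed: int, ablation: frozenset = frozenset()) -> ScoreReport:
    """Held-out AUC on the planted local-anomaly motif set for one seed."""
    return run_holdout_experiment(motif_dataset(seed),
                                  benchmark_config(seed, ablation))


def er_benchmark(seed: int) -> ScoreReport:
    """Held-out AUC on the edge-density contrast set for one seed."""
    return run_holdout_experiment(er_dataset(seed), benchmark_config(seed))


def null_benchmark(seed: int, k: int = 5) -> dict:
    """Cross-validated AUC when anomalies are drawn from the normal model."""
    _, summary = run_cv_experiment(er_dataset(seed, p_anomalous=ER_P_NORMAL),
                                   benchmark_config(seed), k=k, n_repeats=1)
    return summary
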
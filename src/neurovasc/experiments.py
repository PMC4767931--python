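"""Experiment orchestration: synchrony contrast, connectivity and TR sweeps.

Every experiment uses a paired-seed design: the arms being contrasted share
the dataset, the initial autoencoder weights, the vessel-to-neuron wiring
and the data presentation order, so the only manipulated variable is the
vascular regime (epsilon), the projective-field size (z) or the temporal
ratio (TR).  Reports are plain dicts, JSON-serializable, embedding the full
configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .autoencoder import Autoencoder
from .coupling import CoupledTrainer, DemandState, ScheduleParams, build_connectivity
from .datasets import generate_bar_patterns
from .metrics import pairwise_feature_metrics
from .vascular import RingNetwork, VascularParams, compute_apc

__all__ = [
    "ExperimentConfig",
    "train_coupled",
    "measure_ring_apc",
    "run_synchrony_experiment",
    "run_connectivity_sweep",
    "run_temporal_sweep",
    "bar_localization_scores",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full, serializable description of one coupled training run."""

    dataset: str = "bars"
    n_images: int = 5000
    image_size: int = 8
    max_bars: int = 4
    n_hidden: int = 16
    n_vessels: int = 100
    epsilon: float = 0.0
    z: int = 1
    TR: int = 20
    beta: float = 10.0
    learning_rate: float = 0.2
    batch_size: int = 20
    epochs: int = 300
    seed: int = 0
    data_seed: int = 1234
    kernel: str = "gaussian"
    convergence_tol: float = 1e-3
    #: overrides for any other vascular constant (lambda_v, tau_v, sigma, ...)
    vascular: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _bar_pixel_sets(size: int) -> np.ndarray:
    """The 2*size single-bar images, flattened (rows first, then columns)."""
    out = []
    for i in range(size):
        im = np.zeros((size, size))
        im[i, :] = 1.0
        out.append(im.ravel())
    for i in range(size):
        im = np.zeros((size, size))
        im[:, i] = 1.0
        out.append(im.ravel())
    return np.asarray(out)


def bar_localization_scores(W: np.ndarray, size: int) -> np.ndarray:
    """Single-bar concentration of each unit's rectified weight image.

    For each hidden unit the score is the largest fraction of the L1 mass of
    ``max(w, 0)`` that falls on one bar's pixels.  The rectified image is
    used because a trained encoder carries a distributed inhibitory surround
    (it compensates the saturating overlap of crossing bars) that is part of
    the solution, not of the feature's receptive field.  A unit scoring 1.0
    responds to exactly one bar.
    """
    bars = _bar_pixel_sets(size)
    scores = np.zeros(len(W))
    for i, wvec in enumerate(W):
        pos = np.maximum(wvec, 0.0)
        total = pos.sum()
        scores[i] = (bars * pos).sum(axis=1).max() / total if total > 0 else 0.0
    return scores


def train_coupled(config: ExperimentConfig, X: np.ndarray | None = None):
    """Train one coupled run; returns ``(report, net, trainer)``.

    ``X`` may supply a pre-generated flattened dataset (used by the sweeps
    to share data across arms); otherwise it is generated from
    ``config.data_seed``.  The report carries the converged (100-interval
    smoothed) mse, feature metrics, dropout statistics, the training-window
    APC of the vessels and, for bar data, the localization scores.
    """
    cfg = config
    if X is None:
        data = generate_bar_patterns(
            cfg.n_images, cfg.image_size, cfg.max_bars, np.random.default_rng(cfg.data_seed)
        )
        X = data.flattened()
    M = X.shape[1]

    net = Autoencoder(
        M, cfg.n_hidden, learning_rate=cfg.learning_rate, batch_size=cfg.batch_size,
        rng=np.random.default_rng([cfg.seed, 1]),
    )
    params = VascularParams(
        n=cfg.n_vessels, epsilon=cfg.epsilon, kernel=cfg.kernel, **cfg.vascular
    )
    ring = RingNetwork(params, rng=np.random.default_rng([cfg.seed, 2]))
    A = build_connectivity(cfg.n_hidden, cfg.n_vessels, cfg.z, np.random.default_rng([cfg.seed, 3]))
    demand = DemandState(n=cfg.n_vessels, beta=cfg.beta)
    trainer = CoupledTrainer(net, ring, A, demand, ScheduleParams(TR=cfg.TR))

    order_rng = np.random.default_rng([cfg.seed, 4])
    smoothed_prev = None
    converged = False
    epoch_mses = []
    for _ in range(cfg.epochs):
        epoch_mses.append(trainer.run_epoch(X, order_rng))
        smoothed = trainer.smoothed_mse(100)
        if smoothed_prev is not None and smoothed_prev > 0:
            if abs(smoothed - smoothed_prev) / smoothed_prev < cfg.convergence_tol:
                converged = True
        smoothed_prev = smoothed

    side = int(round(np.sqrt(M)))
    fm = pairwise_feature_metrics(net.weight_images((side, side)))
    S_window = trainer.vessel_window()
    try:
        apc = compute_apc(S_window)
    except ValueError:
        apc = float("nan")
    # the demand search wanders on a scale of thousands of intervals, so the
    # converged error is averaged over a window long enough to cover several
    # of its sojourns (capped at half the run for short budgets)
    n_intervals = len(trainer.logs["mse"])
    window = min(15000, max(100, n_intervals // 2))
    report = {
        "config": asdict(cfg),
        "final_mse": trainer.smoothed_mse(window),
        "epoch_mse": epoch_mses,
        "mii_mean": fm.mii_mean,
        "ssi_mean": fm.ssi_mean,
        "apc": apc,
        "q_mean": trainer.dropout_fraction(),
        "q_final": trainer.dropout_fraction(last=1000),
        "N_d_final": demand.N_d,
        "converged": converged,
    }
    if cfg.dataset == "bars":
        scores = bar_localization_scores(net.W, cfg.image_size)
        report["localization_scores"] = scores.tolist()
        report["n_single_bar_units"] = int((scores >= 0.8).sum())
    return report, net, trainer


def measure_ring_apc(
    epsilon: float,
    n: int = 100,
    duration: float = 300.0,
    n_seeds: int = 5,
    seed: int = 0,
    discard_fraction: float = 1.0 / 3.0,
    N_d: float | None = None,
    kernel: str = "gaussian",
) -> list[float]:
    """Average pairwise vessel correlation over several random initializations.

    Runs the closed-loop ring at constant demand (default n/2) for
    ``duration`` time units per seed, discards the initial transient and
    returns one APC per seed.
    """
    params = VascularParams(n=n, epsilon=epsilon, kernel=kernel)
    target = params.n / 2.0 if N_d is None else N_d
    out = []
    for k in range(n_seeds):
        ring = RingNetwork(params, rng=np.random.default_rng([seed, k]))
        _, S = ring.simulate(duration, N_d=target)
        keep = S[:, int(S.shape[1] * discard_fraction):]
        out.append(compute_apc(keep))
    return out


def run_synchrony_experiment(
    config: ExperimentConfig | None = None,
    epsilons: tuple[float, float] = (0.0, 1.0),
) -> dict:
    """Desynchronized vs synchronized arms under one-to-one connectivity.

    Both arms share seeds, data and initial weights; only epsilon differs.
    """
    base = config if config is not None else ExperimentConfig(z=1)
    data = generate_bar_patterns(
        base.n_images, base.image_size, base.max_bars, np.random.default_rng(base.data_seed)
    )
    X = data.flattened()
    arms = {}
    for eps in epsilons:
        report, _, _ = train_coupled(replace(base, epsilon=eps), X=X)
        arms[f"epsilon={eps:g}"] = report
    return {"experiment": "synchrony", "config": asdict(base), "arms": arms}


def run_connectivity_sweep(
    config: ExperimentConfig | None = None,
    z_values: tuple[int, ...] | None = None,
) -> dict:
    """Projective-field sweep from one-to-one (z=1) to complete (z=n), epsilon=0."""
    base = config if config is not None else ExperimentConfig(epsilon=0.0)
    n = base.n_vessels
    if z_values is None:
        z_values = (1, max(1, n // 10), n // 4, n // 2, n)
    data = generate_bar_patterns(
        base.n_images, base.image_size, base.max_bars, np.random.default_rng(base.data_seed)
    )
    X = data.flattened()
    arms = {}
    for z in z_values:
        report, _, _ = train_coupled(replace(base, epsilon=0.0, z=int(z)), X=X)
        arms[f"z={z}"] = report
    return {"experiment": "connectivity", "config": asdict(base),
            "z_values": list(map(int, z_values)), "arms": arms}


def run_temporal_sweep(
    config: ExperimentConfig | None = None,
    TR_values: tuple[int, ...] = (20, 100, 500, 2000),
) -> dict:
    """Temporal-ratio sweep at epsilon=0, z=1.

    Each pattern occupies a fixed slice of vascular time, so larger TR holds
    one dropout mask frozen over more input presentations.
    """
    base = config if config is not None else ExperimentConfig(epsilon=0.0, z=1)
    data = generate_bar_patterns(
        base.n_images, base.image_size, base.max_bars, np.random.default_rng(base.data_seed)
    )
    X = data.flattened()
    arms = {}
    for tr in TR_values:
        report, _, _ = train_coupled(replace(base, TR=int(tr)), X=X)
        arms[f"TR={tr}"] = report
    return {"experiment": "temporal", "config": asdict(base),
            "TR_values": list(map(int, TR_values)), "arms": arms}


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
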
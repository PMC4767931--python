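"""The neurovascular loop: vessels gate hidden units, error drives demand.

Three pieces close the loop between the vascular ring and the autoencoder:

* a fixed random binary connectivity ``A`` (H x n) assigning each hidden
  neuron a *projective field* of exactly ``z`` vessels;
* the vascular -> neural projection: neuron ``i`` is ON for the next interval
  iff the mean state of its ``z`` vessels is positive,
  ``r_i = H(1/z * sum_j a_ij S_j)`` with ``H(0) = 0``;
* the neural -> vascular feedback: the neuronal demand follows a
  finite-difference gradient step on the reconstruction error,
  ``N_d <- N_d - beta * (d mse / d N_d)``, clipped to [-n, n].

Time is organized in *vascular intervals*.  During one interval the ring
advances by a fixed number of Euler substeps, the dropout mask is frozen, and
``TR`` input patterns are presented (grouped into minibatches).  ``TR`` is
the temporal ratio: the number of patterns the neural layer sees per vascular
update.  Each pattern occupies a fixed slice of vascular time, so larger TR
freezes the same mask over proportionally more vascular time.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .autoencoder import Autoencoder
from .vascular import RingNetwork, compute_supply

__all__ = [
    "DemandState",
    "ScheduleParams",
    "CouplingDivergenceError",
    "build_connectivity",
    "compute_neuron_mask",
    "update_demand",
    "CoupledTrainer",
]

#: vascular time units one input pattern occupies (sets the neural/vascular
#: time-scale conversion; one interval advances TR * TIME_PER_PATTERN units)
TIME_PER_PATTERN = 0.05


class CouplingDivergenceError(RuntimeError):
    """Raised when the demand update produces a non-finite value."""


@dataclass
class DemandState:
    """Neuronal demand and the bookkeeping for its finite-difference update.

    ``N_d`` starts at the maximum possible value ``n`` (all vessels ON,
    dropout fraction q = 0).  ``beta`` is the perfusion-rate parameter
    scaling the gradient step.
    """

    n: int
    beta: float = 10.0
    N_d: float = field(init=False)
    mse_prev: float | None = None
    N_d_prev: float | None = None

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        self.N_d = float(self.n)


@dataclass(frozen=True)
class ScheduleParams:
    """Temporal organization of the coupled loop.

    ``TR`` is the temporal ratio (input patterns per vascular interval,
    >= 1).  ``vascular_substeps`` overrides the number of Euler substeps per
    interval; by default it is ``TR * TIME_PER_PATTERN / dt`` so that each
    pattern occupies the same amount of vascular time regardless of TR.
    """

    TR: int = 20
    vascular_substeps: int | None = None

    def __post_init__(self):
        if self.TR < 1:
            raise ValueError("TR must be a positive integer")
        if self.vascular_substeps is not None and self.vascular_substeps < 1:
            raise ValueError("vascular_substeps must be a positive integer")

    def substeps(self, dt: float) -> int:
        if self.vascular_substeps is not None:
            return self.vascular_substeps
        return max(1, int(round(self.TR * TIME_PER_PATTERN / dt)))


def build_connectivity(H: int, n: int, z: int, rng: np.random.Generator) -> np.ndarray:
    """H x n binary matrix; each row holds exactly ``z`` ones, drawn uniformly.

    ``z = 1`` gives one-to-one-style connectivity (each neuron listens to a
    single vessel), ``z = n`` complete connectivity (every neuron receives
    the same feedback and all stochasticity is lost).
    """
    if not 1 <= z <= n:
        raise ValueError(f"projective field z={z} must lie in [1, {n}]")
    A = np.zeros((H, n))
    for i in range(H):
        A[i, rng.choice(n, size=z, replace=False)] = 1.0
    return A


def compute_neuron_mask(S: np.ndarray, A: np.ndarray, z: int) -> np.ndarray:
    """Dropout mask from vessel states: ``r_i = H(mean of neuron i's vessels)``.

    Heaviside with the OFF-on-tie convention H(0) = 0: a neuron fires in the
    coming interval only if the average perfusion of its projective field is
    strictly positive.
    """
    S = np.asarray(S, dtype=float)
    if A.shape[1] != S.shape[0]:
        raise ValueError(f"connectivity has {A.shape[1]} vessels, states {S.shape[0]}")
    return ((A @ S) / z > 0.0).astype(float)


def update_demand(demand: DemandState, mse_current: float) -> DemandState:
    """One finite-difference gradient step on the demand, in place.

    ``N_d <- N_d - beta * (Delta mse / Delta N_d)`` with three safeguards:
    the very first interval takes a fixed probe step of -1 (nudging away
    from the all-ON start); when ``|Delta N_d| < 1e-6`` the ratio is
    undefined and a probe step of magnitude 0.1 is taken opposite to the
    sign of ``Delta mse``; otherwise the ratio magnitude is clipped to
    ``10/beta`` (bounding any single step by 10 demand units).  The result
    is clipped to [0, n]: demand cannot be negative, and n (every vessel
    saturated ON) is the most the supply can deliver.
    """
    if not np.isfinite(mse_current):
        raise CouplingDivergenceError(f"non-finite interval mse {mse_current}")
    n = demand.n
    if demand.mse_prev is None:
        step = -1.0
    else:
        d_mse = mse_current - demand.mse_prev
        d_Nd = demand.N_d - (demand.N_d_prev if demand.N_d_prev is not None else demand.N_d)
        if abs(d_Nd) < 1e-6:
            step = -0.1 * np.sign(d_mse) if d_mse != 0.0 else -0.1
        else:
            cap = 10.0 / demand.beta
            ratio = float(np.clip(d_mse / d_Nd, -cap, cap))
            step = -demand.beta * ratio
    if not np.isfinite(step):
        raise CouplingDivergenceError("demand update diverged")
    demand.N_d_prev = demand.N_d
    demand.mse_prev = mse_current
    demand.N_d = float(np.clip(demand.N_d + step, 0.0, n))
    return demand


class CoupledTrainer:
    """Runs the closed neurovascular training loop.

    One vascular interval repeats the cycle: (1) advance the ring in closed
    loop under the current demand, (2) freeze the dropout mask from the
    vessel states, (3) present TR patterns as minibatches under that mask,
    accumulating reconstruction error and updating weights, (4) update the
    demand from the interval's error.  Per-interval logs record mse, the
    dropout fraction q, demand, supply, accumulated deficit and drive, plus a
    sliding window of vessel states for synchrony measurements.
    """

    def __init__(
        self,
        net: Autoencoder,
        ring: RingNetwork,
        connectivity: np.ndarray,
        demand: DemandState,
        schedule: ScheduleParams | None = None,
        apc_window: int = 2000,
    ):
        if connectivity.shape[0] != net.H:
            raise ValueError("connectivity rows must match hidden layer size")
        if connectivity.shape[1] != ring.params.n:
            raise ValueError("connectivity columns must match vessel count")
        self.net = net
        self.ring = ring
        self.A = connectivity
        self.z = int(connectivity[0].sum())
        self.demand = demand
        self.schedule = schedule if schedule is not None else ScheduleParams()
        self.logs: dict[str, list] = {k: [] for k in ("mse", "q", "N_d", "N_s", "E", "I")}
        self.mask_history: deque = deque(maxlen=apc_window)
        self.S_window: deque = deque(maxlen=apc_window)

    def run_interval(self, patterns: np.ndarray) -> float:
        """One vascular interval over ``patterns`` (TR x M); returns its mse."""
        substeps = self.schedule.substeps(self.ring.params.dt)
        self.ring.advance(substeps, N_d=self.demand.N_d)
        S = self.ring.state.S
        mask = compute_neuron_mask(S, self.A, self.z)
        bt = self.net.batch_size
        mses = []
        for start in range(0, len(patterns), bt):
            batch = patterns[start : start + bt]
            mses.append(self.net.train_step(batch, mask))
        interval_mse = float(np.mean(mses))
        update_demand(self.demand, interval_mse)
        self.logs["mse"].append(interval_mse)
        self.logs["q"].append(1.0 - float(mask.mean()))
        self.logs["N_d"].append(self.demand.N_d)
        self.logs["N_s"].append(compute_supply(S))
        self.logs["E"].append(self.ring.state.E)
        self.logs["I"].append(self.ring.state.I)
        self.mask_history.append(mask.copy())
        self.S_window.append(S.copy())
        return interval_mse

    def run_epoch(self, X: np.ndarray, rng: np.random.Generator, shuffle: bool = True) -> float:
        """One pass over the flattened dataset ``X``; returns the epoch's mean mse."""
        order = rng.permutation(len(X)) if shuffle else np.arange(len(X))
        TR = self.schedule.TR
        epoch_mses = []
        for start in range(0, len(X) - TR + 1, TR):
            patterns = X[order[start : start + TR]]
            epoch_mses.append(self.run_interval(patterns))
        return float(np.mean(epoch_mses))

    # ------------------------------------------------------------------ summaries

    def dropout_fraction(self, last: int | None = None) -> float:
        q = self.logs["q"][-last:] if last else self.logs["q"]
        return float(np.mean(q))

    def smoothed_mse(self, window: int = 100) -> float:
        tail = self.logs["mse"][-window:]
        return float(np.mean(tail))

    def vessel_window(self) -> np.ndarray:
        """Vessel states over the retained window, shape n x intervals."""
        return np.asarray(self.S_window).T

    def mask_matrix(self) -> np.ndarray:
        """Mask history over the retained window, shape H x intervals."""
        return np.asarray(self.mask_history).T

    def save_log_csv(self, path) -> None:
        keys = list(self.logs)
        rows = len(self.logs["mse"])
        with open(path, "w") as fh:
            fh.write("interval," + ",".join(keys) + "\n")
            for k in range(rows):
                fh.write(str(k) + "," + ",".join(f"{self.logs[key][k]:.8g}" for key in keys) + "\n")
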
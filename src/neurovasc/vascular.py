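"""Ring network of coupled vascular oscillators.

Each of the ``n`` vessels carries three variables: a supporting variable
``g``, an activity-history variable ``u`` and the vessel state
``S = tanh(lambda_v * g)`` in (-1, 1), read as the perfusion level (+1 fully
ON, -1 fully OFF).  Vessels sit on a ring of radius ``rho`` and interact
laterally through a distance-dependent coupling matrix ``T`` whose
excitation/inhibition balance is set by ``epsilon`` in [0, 2]:

* ``epsilon = 0`` — purely inhibitory lateral interactions.  The ring
  oscillates chaotically and the vessels desynchronize (average pairwise
  correlation near 0).
* ``epsilon = 2`` — all interactions excitatory; intermediate values such as
  ``epsilon = 1`` already lock the ring into synchronized oscillation
  (average pairwise correlation near 1).

The ring is driven by a scalar deficit signal ``I = E - n/2`` where the
accumulated deficit ``E`` integrates ``tanh(lambda_e * e)`` of the
instantaneous deficit ``e = N_d - N_s`` between the neuronal demand ``N_d``
and the vascular supply ``N_s = sum_j S_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

try:  # compiled inner loop; falls back to pure NumPy when numba is absent
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None

__all__ = [
    "VascularParams",
    "VascularState",
    "NumericalInstabilityError",
    "ConstantTraceError",
    "build_ring_geometry",
    "build_coupling_matrix",
    "step_vascular",
    "compute_supply",
    "update_deficit",
    "compute_apc",
    "RingNetwork",
]


class NumericalInstabilityError(RuntimeError):
    """Raised when the explicit-Euler update produces non-finite state."""


class ConstantTraceError(ValueError):
    """Raised when a vessel trace has zero variance and correlation is undefined."""

    def __init__(self, vessel: int):
        self.vessel = vessel
        super().__init__(
            f"vessel {vessel} has a constant state trace; "
            "pairwise correlation is undefined"
        )


@dataclass(frozen=True)
class VascularParams:
    """Parameters of the vascular ring.

    ``sigma`` defaults to 1.5 inter-vessel spacings ``1.5 * rho * 2*pi / n``:
    wide enough that lateral inhibition frustrates several neighbours, which
    puts the ``epsilon = 0`` ring in its most strongly chaotic regime (the
    dropout patterns it generates are maximally diverse), while remaining
    short-range.  ``lambda_v = 7`` is chosen for the same reason.  ``kernel``
    selects the exponent of the coupling kernel: ``"gaussian"`` uses
    ``exp(-d^2/sigma^2)`` (default; the only form that yields a
    desynchronized regime at ``epsilon = 0``), ``"printed"`` uses
    ``exp(-d/sigma^2)``.  ``self_coupling`` re-enables the diagonal entry
    ``epsilon - 2`` of the coupling matrix; by default vessels do not couple
    to themselves.
    """

    n: int = 100
    epsilon: float = 0.0
    rho: float = 1.0
    sigma: float | None = None
    lambda_v: float = 7.0
    tau_v: float = 5.0
    tau_e: float = 10.0
    lambda_e: float = 1.0
    dt: float = 0.01
    kernel: Literal["gaussian", "printed"] = "gaussian"
    self_coupling: bool = False

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"need at least 2 vessels, got n={self.n}")
        if not 0.0 <= self.epsilon <= 2.0:
            raise ValueError(f"epsilon must lie in [0, 2], got {self.epsilon}")
        for name in ("rho", "lambda_v", "tau_v", "tau_e", "lambda_e", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be strictly positive")
        if self.kernel not in ("gaussian", "printed"):
            raise ValueError(f"unknown kernel {self.kernel!r}")

    @property
    def sigma_value(self) -> float:
        """Effective kernel width: ``sigma`` or 1.5 inter-vessel spacings."""
        if self.sigma is not None:
            return self.sigma
        return 1.5 * self.rho * 2.0 * np.pi / self.n


@dataclass
class VascularState:
    """Dynamical state of the ring: per-vessel g, u, S plus scalar E and I."""

    g: np.ndarray
    u: np.ndarray
    S: np.ndarray
    E: float
    I: float

    def copy(self) -> "VascularState":
        return VascularState(self.g.copy(), self.u.copy(), self.S.copy(), self.E, self.I)


def build_ring_geometry(n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Place ``n`` vessels evenly on a ring of radius ``rho``.

    Returns the angular positions ``alpha_j = 2*pi*(j-1)/n`` and the symmetric
    matrix of pairwise chord distances
    ``d_jk = rho * sqrt((cos a_j - cos a_k)^2 + (sin a_j - sin a_k)^2)``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 vessels, got n={n}")
    if rho <= 0:
        raise ValueError(f"ring radius must be positive, got rho={rho}")
    angles = 2.0 * np.pi * np.arange(n) / n
    dc = np.cos(angles)[:, None] - np.cos(angles)[None, :]
    ds = np.sin(angles)[:, None] - np.sin(angles)[None, :]
    distances = rho * np.sqrt(dc**2 + ds**2)
    return angles, distances


def build_coupling_matrix(
    distances: np.ndarray,
    epsilon: float,
    sigma: float,
    kernel: str = "gaussian",
    self_coupling: bool = False,
) -> np.ndarray:
    """Lateral coupling ``T_jk = epsilon - 2*exp(-f(d_jk))`` cut off at 3*sigma.

    ``f(d) = d^2/sigma^2`` for the ``"gaussian"`` kernel, ``d/sigma^2`` for
    the ``"printed"`` variant.  Entries beyond the cutoff are zero.  Unless
    ``self_coupling`` is set, the diagonal is zeroed: vessels are mutually
    coupled but not self-coupled.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not 0.0 <= epsilon <= 2.0:
        raise ValueError(f"epsilon must lie in [0, 2], got {epsilon}")
    d = np.asarray(distances, dtype=float)
    if kernel == "gaussian":
        expo = d**2 / sigma**2
    elif kernel == "printed":
        expo = d / sigma**2
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    T = np.where(d < 3.0 * sigma, epsilon - 2.0 * np.exp(-expo), 0.0)
    if not self_coupling:
        np.fill_diagonal(T, 0.0)
    return T


def step_vascular(
    state: VascularState,
    params: VascularParams,
    T: np.ndarray,
    I: float,
) -> VascularState:
    """One explicit-Euler step of the vessel dynamics under deficit signal ``I``.

    dg_j/dt = -g_j - u_j + sum_k T_jk S_k + I
    tau_v du_j/dt = -u_j + S_j
    S_j = tanh(lambda_v g_j)

    The scalar ``I`` is broadcast to every vessel.  Raises
    :class:`NumericalInstabilityError` if the update leaves the finite range.
    """
    dt = params.dt
    g = state.g + dt * (-state.g - state.u + T @ state.S + I)
    u = state.u + (dt / params.tau_v) * (-state.u + state.S)
    if not (np.all(np.isfinite(g)) and np.all(np.isfinite(u))):
        raise NumericalInstabilityError(
            f"non-finite vessel state after Euler step (dt={dt}); reduce dt"
        )
    S = np.tanh(params.lambda_v * g)
    return VascularState(g=g, u=u, S=S, E=state.E, I=I)


def compute_supply(S: np.ndarray) -> float:
    """Vascular supply ``N_s = sum_j S_j``; lies in (-n, n)."""
    return float(np.sum(S))


def update_deficit(
    E: float,
    N_d: float,
    N_s: float,
    params: VascularParams,
) -> tuple[float, float, float]:
    """Advance the accumulated deficit one step.

    e = N_d - N_s
    E <- E + (dt/tau_e) * tanh(lambda_e * e)
    I = E - n/2

    Returns ``(e, E_new, I)``.
    """
    e = N_d - N_s
    E_new = E + (params.dt / params.tau_e) * np.tanh(params.lambda_e * e)
    I = E_new - params.n / 2.0
    return e, float(E_new), float(I)


def compute_apc(S_history: np.ndarray) -> float:
    """Average pairwise correlation of vessel-state time series.

    ``S_history`` is an ``n x t`` matrix.  The Pearson correlation
    ``gamma_jk`` is computed for every ordered pair ``j != k`` and averaged
    over all ``n*(n-1)`` pairs.  Raises :class:`ConstantTraceError` naming the
    first vessel whose trace has zero variance.
    """
    S_history = np.asarray(S_history, dtype=float)
    if S_history.ndim != 2 or S_history.shape[0] < 2 or S_history.shape[1] < 2:
        raise ValueError("need an n x t matrix with n >= 2 vessels and t >= 2 samples")
    spread = np.ptp(S_history, axis=1)
    zero = np.flatnonzero(spread == 0.0)
    if zero.size:
        raise ConstantTraceError(int(zero[0]))
    C = np.corrcoef(S_history)
    n = S_history.shape[0]
    return float((C.sum() - np.trace(C)) / (n * (n - 1)))


def _euler_loop_py(g, u, idx, w, E, dt, tau_v, lambda_v, tau_e, lambda_e, n_half,
                   substeps, closed, N_d, I_const):
    """Inner Euler loop with the coupling matrix in sparse row form.

    ``idx``/``w`` hold, per vessel, the column indices and weights of the
    nonzero couplings (zero-padded); identical math to
    :func:`step_vascular` + :func:`update_deficit`.
    """
    n = g.shape[0]
    S = np.tanh(lambda_v * g)
    K = idx.shape[1]
    for _ in range(substeps):
        I = (E - n_half) if closed else I_const
        g_new = np.empty(n)
        for j in range(n):
            acc = 0.0
            for k in range(K):
                acc += w[j, k] * S[idx[j, k]]
            g_new[j] = g[j] + dt * (-g[j] - u[j] + acc + I)
        u = u + (dt / tau_v) * (-u + S)
        g = g_new
        S = np.tanh(lambda_v * g)
        if closed:
            E = E + (dt / tau_e) * np.tanh(lambda_e * (N_d - S.sum()))
    return g, u, S, E, (E - n_half) if closed else I_const


if njit is not None:
    _euler_loop = njit(cache=False)(_euler_loop_py)
else:  # pragma: no cover
    _euler_loop = _euler_loop_py


def _sparse_rows(T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded per-row index/weight arrays of the nonzero entries of T."""
    n = T.shape[0]
    K = max(1, int((T != 0).sum(axis=1).max()))
    idx = np.zeros((n, K), dtype=np.int64)
    w = np.zeros((n, K))
    for j in range(n):
        cols = np.flatnonzero(T[j])
        idx[j, : cols.size] = cols
        w[j, : cols.size] = T[j, cols]
    return idx, w


class RingNetwork:
    """Stateful vascular ring: geometry, coupling and closed-loop simulation.

    The network is driven either by an externally supplied constant deficit
    signal ``I`` or, in closed-loop mode, by a (possibly time-varying) demand
    ``N_d`` through the deficit accumulator.  Initial conditions draw ``g``
    and ``u`` uniformly from [-0.01, 0.01] to break symmetry; the accumulated
    deficit starts at ``E = n/2`` so the deficit signal starts at ``I = 0``.
    """

    def __init__(self, params: VascularParams, rng: np.random.Generator | None = None):
        self.params = params
        self.angles, self.distances = build_ring_geometry(params.n, params.rho)
        self.T = build_coupling_matrix(
            self.distances,
            params.epsilon,
            params.sigma_value,
            kernel=params.kernel,
            self_coupling=params.self_coupling,
        )
        self._idx, self._w = _sparse_rows(self.T)
        self.rng = rng if rng is not None else np.random.default_rng()
        self.state = self.initial_state(self.rng)

    def initial_state(self, rng: np.random.Generator) -> VascularState:
        n = self.params.n
        g = rng.uniform(-0.01, 0.01, n)
        u = rng.uniform(-0.01, 0.01, n)
        return VascularState(
            g=g,
            u=u,
            S=np.tanh(self.params.lambda_v * g),
            E=n / 2.0,
            I=0.0,
        )

    def reset(self, rng: np.random.Generator | None = None) -> None:
        if rng is not None:
            self.rng = rng
        self.state = self.initial_state(self.rng)

    def advance(self, substeps: int, N_d: float | None = None, I: float | None = None) -> None:
        """Advance the ring by ``substeps`` Euler steps.

        In closed-loop mode (``N_d`` given) the deficit accumulator is updated
        every step and generates the drive; alternatively a constant ``I``
        may be imposed directly.  Exactly one of the two must be provided.
        """
        if (N_d is None) == (I is None):
            raise ValueError("provide exactly one of N_d (closed loop) or I (imposed drive)")
        st = self.state
        p = self.params
        closed = N_d is not None
        g, u, S, E, drive = _euler_loop(
            st.g, st.u, self._idx, self._w, float(st.E), p.dt, p.tau_v, p.lambda_v,
            p.tau_e, p.lambda_e, p.n / 2.0, substeps, closed,
            float(N_d) if closed else 0.0, float(I) if I is not None else 0.0,
        )
        if not (np.all(np.isfinite(g)) and np.all(np.isfinite(u))):
            raise NumericalInstabilityError(
                f"non-finite vessel state after Euler step (dt={p.dt}); reduce dt"
            )
        self.state = VascularState(g=g, u=u, S=S, E=float(E), I=float(drive))

    def simulate(
        self,
        duration: float,
        N_d: float | None = None,
        I: float | None = None,
        record_every: int = 10,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Run for ``duration`` time units, recording S every ``record_every`` steps.

        Returns ``(t, S_history)`` with ``S_history`` of shape
        ``n x n_samples``.  Defaults to closed-loop operation at the constant
        demand ``N_d = n/2`` when neither drive is given, the regime in which
        both the synchronized and the desynchronized ring oscillate.
        """
        if N_d is None and I is None:
            N_d = self.params.n / 2.0
        steps = int(round(duration / self.params.dt))
        times, hist = [], []
        for k in range(steps):
            self.advance(1, N_d=N_d, I=I)
            if k % record_every == 0:
                times.append((k + 1) * self.params.dt)
                hist.append(self.state.S.copy())
        return np.asarray(times), np.asarray(hist).T

    def save_trajectory_csv(self, path, t: np.ndarray, S_history: np.ndarray) -> None:
        """Write a long-format trajectory table (t, vessel, S) to CSV."""
        n, m = S_history.shape
        with open(path, "w") as fh:
            fh.write("t,vessel,S\n")
            for k in range(m):
                for j in range(n):
                    fh.write(f"{t[k]:.6g},{j},{S_history[j, k]:.8g}\n")


def _replace_params(params: VascularParams, **kwargs) -> VascularParams:
    """Convenience for sweeps: a copy of ``params`` with fields replaced."""
    return replace(params, **kwargs)
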
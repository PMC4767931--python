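"""Rate-coded single-hidden-layer autoencoder with externally gated dropout.

The network maps an input ``x`` (length M) through H rectified-linear hidden
units and reconstructs it at a rectified-linear output layer:

    h = W x + b,  v = relu(h),  v_new = v * r,  y_new = relu(Z v_new + B)

``r`` is a binary dropout mask supplied from outside — in the coupled model it
comes from the vascular ring, as a baseline from a Bernoulli draw.  There is
no inverted-dropout rescaling: the mask enters as a bare elementwise product
and the reported reconstruction error is measured with the mask in force.

The reconstruction error over a minibatch of ``bt`` patterns is

    mse = 1/(2*bt*M) * sum_P sum_m (x_m - y_m_new)^2

and training is plain minibatch SGD on its gradients, with dropped units
receiving zero gradient through ``v_new``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["relu", "compute_mse", "bernoulli_mask", "Autoencoder", "DivergenceError"]


class DivergenceError(RuntimeError):
    """Raised when a gradient or parameter block becomes non-finite."""


def relu(h: np.ndarray) -> np.ndarray:
    """Rectified-linear activation, elementwise max(0, h); f(0) = 0."""
    return np.maximum(h, 0.0)


def compute_mse(X_batch: np.ndarray, Y_batch: np.ndarray) -> float:
    """Reconstruction error ``1/(2*bt*M) * sum((X - Y)^2)`` over a batch.

    ``X_batch`` and ``Y_batch`` are ``bt x M`` arrays of inputs and
    reconstructions.  Raises on an empty batch.
    """
    X = np.atleast_2d(np.asarray(X_batch, dtype=float))
    Y = np.atleast_2d(np.asarray(Y_batch, dtype=float))
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    bt, M = X.shape
    if bt == 0 or M == 0:
        raise ValueError("empty batch")
    return float(np.sum((X - Y) ** 2) / (2.0 * bt * M))


def bernoulli_mask(H: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Binary mask with each unit ON independently with probability ``p``.

    The non-vascular control: classic Bernoulli dropout with OFF fraction
    ``q = 1 - p``.  Requires ``0 < p < 1``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    return (rng.random(H) < p).astype(float)


@dataclass
class _Gradients:
    W: np.ndarray
    b: np.ndarray
    Z: np.ndarray
    B: np.ndarray


class Autoencoder:
    """M -> H -> M autoencoder with ReLU hidden and output units.

    Weights are initialized uniformly in ``[-1/sqrt(fan_in), 1/sqrt(fan_in)]``
    from the supplied generator; biases start at zero.
    """

    def __init__(
        self,
        n_visible: int,
        n_hidden: int,
        learning_rate: float = 0.2,
        batch_size: int = 20,
        rng: np.random.Generator | None = None,
    ):
        if n_visible < 1 or n_hidden < 1:
            raise ValueError("layer sizes must be positive")
        if learning_rate < 0:
            raise ValueError("learning rate must be nonnegative")
        rng = rng if rng is not None else np.random.default_rng()
        self.M = n_visible
        self.H = n_hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        lim_in = 1.0 / np.sqrt(n_visible)
        lim_h = 1.0 / np.sqrt(n_hidden)
        self.W = rng.uniform(-lim_in, lim_in, (n_hidden, n_visible))
        self.b = np.zeros(n_hidden)
        self.Z = rng.uniform(-lim_h, lim_h, (n_visible, n_hidden))
        self.B = np.zeros(n_visible)

    # ------------------------------------------------------------------ forward

    def forward(
        self, x: np.ndarray, mask: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Forward pass for one pattern or a batch.

        Returns ``(h, v, v_new, y_new)``: hidden pre-activation, hidden
        activity, masked hidden activity, and the rectified reconstruction.
        ``mask`` defaults to all-ones (no dropout).
        """
        x = np.asarray(x, dtype=float)
        batched = x.ndim == 2
        X = np.atleast_2d(x)
        if X.shape[1] != self.M:
            raise ValueError(f"input length {X.shape[1]} != {self.M}")
        r = np.ones(self.H) if mask is None else np.asarray(mask, dtype=float)
        if r.shape != (self.H,):
            raise ValueError(f"mask length {r.shape} != ({self.H},)")
        h = X @ self.W.T + self.b
        v = relu(h)
        v_new = v * r
        y_new = relu(v_new @ self.Z.T + self.B)
        if batched:
            return h, v, v_new, y_new
        return h[0], v[0], v_new[0], y_new[0]

    def reconstruction_mse(self, X: np.ndarray, mask: np.ndarray | None = None) -> float:
        """Batch reconstruction error, by default mask-free (diagnostic mode)."""
        _, _, _, Y = self.forward(np.atleast_2d(X), mask)
        return compute_mse(np.atleast_2d(X), Y)

    # ------------------------------------------------------------------ training

    def _gradients(self, X: np.ndarray, mask: np.ndarray) -> tuple[_Gradients, float]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        bt = X.shape[0]
        r = np.asarray(mask, dtype=float)
        h = X @ self.W.T + self.b
        v = relu(h)
        v_new = v * r
        ypre = v_new @ self.Z.T + self.B
        y = relu(ypre)
        diff = y - X
        mse = float(np.sum(diff**2) / (2.0 * bt * self.M))
        # subgradient convention: relu'(0) = 0
        dy = diff * (ypre > 0) / (bt * self.M)
        gZ = dy.T @ v_new
        gB = dy.sum(axis=0)
        dv = (dy @ self.Z) * r * (h > 0)
        gW = dv.T @ X
        gb = dv.sum(axis=0)
        return _Gradients(gW, gb, gZ, gB), mse

    def train_step(self, X_batch: np.ndarray, mask: np.ndarray | None = None) -> float:
        """One SGD update on a minibatch under a frozen dropout mask.

        Returns the pre-update reconstruction error of the batch (mask in
        force).  Raises :class:`DivergenceError` if any gradient block is
        non-finite, naming the block.
        """
        r = np.ones(self.H) if mask is None else mask
        grads, mse = self._gradients(X_batch, r)
        for name in ("W", "b", "Z", "B"):
            gblock = getattr(grads, name)
            if not np.all(np.isfinite(gblock)):
                raise DivergenceError(f"non-finite gradient in parameter block {name}")
        lr = self.learning_rate
        self.W -= lr * grads.W
        self.b -= lr * grads.b
        self.Z -= lr * grads.Z
        self.B -= lr * grads.B
        return mse

    # ------------------------------------------------------------------ weights I/O

    def weight_images(self, shape: tuple[int, int]) -> np.ndarray:
        """Encoder weight vectors reshaped into images, one per hidden unit."""
        if shape[0] * shape[1] != self.M:
            raise ValueError(f"shape {shape} incompatible with {self.M} inputs")
        return self.W.reshape(self.H, *shape)

    def save_weight_grid(self, path, shape: tuple[int, int]) -> None:
        """Write the hidden units' weight images as a PNG tile grid.

        Requires matplotlib (optional dependency); each tile is one unit's
        incoming weight vector reshaped to the input image shape.
        """
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        imgs = self.weight_images(shape)
        cols = int(np.ceil(np.sqrt(self.H)))
        rows = int(np.ceil(self.H / cols))
        fig, axes = plt.subplots(rows, cols, figsize=(cols, rows))
        for k, ax in enumerate(np.atleast_1d(axes).ravel()):
            ax.axis("off")
            if k < self.H:
                ax.imshow(imgs[k], cmap="gray")
        fig.tight_layout(pad=0.2)
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def save(self, path) -> None:
        """Checkpoint W, b, Z, B and hyperparameters to an NPZ archive."""
        np.savez(
            path,
            W=self.W,
            b=self.b,
            Z=self.Z,
            B=self.B,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
        )

    @classmethod
    def load(cls, path) -> "Autoencoder":
        data = np.load(path)
        net = cls.__new__(cls)
        net.W = data["W"]
        net.b = data["b"]
        net.Z = data["Z"]
        net.B = data["B"]
        net.H, net.M = net.W.shape
        net.learning_rate = float(data["learning_rate"])
        net.batch_size = int(data["batch_size"])
        return net
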
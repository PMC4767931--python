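"""Feature-quality metrics over learned weight images.

Two pairwise measures quantify how independent the features learned by the
hidden units are:

* **MII** (mutual information index): ``MII = S(X) + S(Y) - S(X, Y)``, with
  marginal entropies from per-image pixel histograms and the joint entropy
  from the 2-D histogram.  Low MII across pairs indicates independent
  features.
* **SSI** (structural similarity index), single-window form:

  ``SSI = (2 mu_x mu_y + C1)(2 cov_xy + C2) /
          ((mu_x^2 + mu_y^2 + C1)(sd_x^2 + sd_y^2 + C2))``

Histograms use 16 equal-width bins over the pooled min-max range of the two
images being compared; entropies are in bits.  ``C1 = (0.01 L)^2`` and
``C2 = (0.03 L)^2`` with ``L`` the pooled dynamic range.  Weight images are
min-max normalized to [0, 1] before either metric since raw weights are
unbounded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["entropy", "mii", "ssi", "pairwise_feature_metrics", "FeatureMetrics", "normalize01"]

DEFAULT_BINS = 16


def normalize01(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi <= lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def _bin_edges(lo: float, hi: float, bins: int) -> np.ndarray:
    if hi <= lo:  # degenerate range: a single occupied bin
        hi = lo + 1.0
    return np.linspace(lo, hi, bins + 1)


def entropy(image: np.ndarray, bins: int = DEFAULT_BINS, range_: tuple[float, float] | None = None) -> float:
    """Shannon entropy (bits) of the pixel histogram.

    ``range_`` fixes the binning range; by default the image's own min-max
    is used.  A constant image occupies a single bin and has zero entropy.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    x = np.asarray(image, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty image")
    lo, hi = range_ if range_ is not None else (x.min(), x.max())
    counts, _ = np.histogram(x, bins=_bin_edges(lo, hi, bins))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def mii(X: np.ndarray, Y: np.ndarray, bins: int = DEFAULT_BINS) -> float:
    """Mutual information index between two images of identical shape.

    Marginal and joint entropies share one equal-width binning over the
    pooled min-max range of both images, so ``mii(X, X) = entropy(X)`` and
    the result is nonnegative up to floating error.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    lo = float(min(X.min(), Y.min()))
    hi = float(max(X.max(), Y.max()))
    edges = _bin_edges(lo, hi, bins)
    SX = entropy(X, bins, range_=(lo, hi))
    SY = entropy(Y, bins, range_=(lo, hi))
    joint, _, _ = np.histogram2d(X.ravel(), Y.ravel(), bins=[edges, edges])
    p = joint[joint > 0] / X.size
    SXY = float(-(p * np.log2(p)).sum())
    return SX + SY - SXY


def ssi(X: np.ndarray, Y: np.ndarray, C1: float | None = None, C2: float | None = None) -> float:
    """Single-window structural similarity between two images.

    Uses means, standard deviations and the cross covariance over all
    pixels (no sliding window).  When ``C1``/``C2`` are not given they
    default to ``(0.01 L)^2`` and ``(0.03 L)^2`` with ``L`` the pooled
    dynamic range of the pair (or 1 for a pair of constants).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    L = float(max(X.max(), Y.max()) - min(X.min(), Y.min()))
    if L <= 0:
        L = 1.0
    c1 = (0.01 * L) ** 2 if C1 is None else C1
    c2 = (0.03 * L) ** 2 if C2 is None else C2
    if c1 <= 0 or c2 <= 0:
        raise ValueError("C1 and C2 must be positive")
    mx, my = X.mean(), Y.mean()
    vx, vy = X.var(), Y.var()
    cxy = float(((X - mx) * (Y - my)).mean())
    return float(
        (2 * mx * my + c1) * (2 * cxy + c2) / ((mx * mx + my * my + c1) * (vx + vy + c2))
    )


@dataclass
class FeatureMetrics:
    """Pairwise MII/SSI matrices over H weight images and their off-diagonal means."""

    mii_matrix: np.ndarray
    ssi_matrix: np.ndarray
    mii_mean: float
    ssi_mean: float


def pairwise_feature_metrics(
    weight_images: np.ndarray,
    bins: int = DEFAULT_BINS,
    C1: float | None = None,
    C2: float | None = None,
    normalize: bool = True,
) -> FeatureMetrics:
    """MII and SSI over all unordered pairs of ``H >= 2`` weight images.

    Images are min-max normalized to [0, 1] first (disable with
    ``normalize=False`` for already-scaled inputs).  The scalar summaries
    are the off-diagonal means of the two symmetric matrices.
    """
    imgs = np.asarray(weight_images, dtype=float)
    H = len(imgs)
    if H < 2:
        raise ValueError("need at least 2 weight images")
    if normalize:
        imgs = np.stack([normalize01(im) for im in imgs])
    M = np.zeros((H, H))
    S = np.eye(H)
    for i in range(H):
        M[i, i] = entropy(imgs[i], bins)
        for j in range(i + 1, H):
            M[i, j] = M[j, i] = mii(imgs[i], imgs[j], bins)
            S[i, j] = S[j, i] = ssi(imgs[i], imgs[j], C1, C2)
    off = ~np.eye(H, dtype=bool)
    return FeatureMetrics(
        mii_matrix=M,
        ssi_matrix=S,
        mii_mean=float(M[off].mean()),
        ssi_mean=float(S[off].mean()),
    )
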
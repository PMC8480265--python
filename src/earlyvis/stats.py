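"""Distribution-level comparisons: kernel densities, KL divergence, Gini sparsity.

KL divergence is computed in bits between Gaussian-kernel density estimates
(Silverman bandwidth) of a reference sample (e.g., physiological
measurements) and a model sample of the same variable:

    D_KL(P || Q) = integral p(x) log2(p(x) / q(x)) dx

with p the reference density.  Sparseness of a population code is measured
by the Gini index, 1 - 2 * integral of the Lorenz curve: 0 when every unit
responds equally, approaching 1 when a single unit carries all activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde


@dataclass
class DensityEstimate:
    """KDE of a 1-D or 2-D sample on a regular evaluation grid."""

    variables: list[str]
    axes: list[np.ndarray]          # one axis per dimension
    density: np.ndarray             # shape = tuple(len(ax) for ax in axes)
    kde: gaussian_kde
    sample: np.ndarray              # (n, dim)

    @property
    def dim(self) -> int:
        return len(self.axes)

    def integral(self) -> float:
        z = self.density
        for ax in reversed(self.axes):
            z = np.trapezoid(z, ax, axis=-1)
        return float(z)


def estimate_pdf(
    sample,
    variables: list[str] | None = None,
    grid_points: int | None = None,
    pad: float = 0.1,
    bw_method: str = "silverman",
) -> DensityEstimate:
    """Gaussian-kernel density with Silverman bandwidth.

    ``sample`` is (n,) or (n, dim) with dim in {1, 2} (or a ReferenceSample).
    The grid spans the sample range padded by ``pad`` on each side, with 256
    points in 1-D and 128 per axis in 2-D.
    """
    values = getattr(sample, "values", sample)
    if variables is None:
        variables = getattr(sample, "variables", None)
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, dim = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if dim not in (1, 2):
        raise ValueError("only 1-D and 2-D densities are supported")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance sample: density is degenerate")
    if variables is None:
        variables = [f"x{i}" for i in range(dim)]
    if grid_points is None:
        grid_points = 256 if dim == 1 else 128
    kde = gaussian_kde(X.T, bw_method=bw_method)
    axes = []
    for d in range(dim):
        lo, hi = X[:, d].min(), X[:, d].max()
        span = (hi - lo) or 1.0
        # widen by the kernel bandwidth so the density integrates to ~1 on
        # the grid even for tiny samples
        bw = 4.0 * np.sqrt(kde.covariance[d, d])
        ext = max(pad * span, bw)
        axes.append(np.linspace(lo - ext, hi + ext, grid_points))
    if dim == 1:
        dens = kde(axes[0][None, :])
    else:
        gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
        dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    return DensityEstimate(variables=list(variables), axes=axes, density=dens,
                           kde=kde, sample=X)


def kl_divergence(p: DensityEstimate, q: DensityEstimate,
                  floor: float = 1e-12, grid_points: int | None = None) -> float:
    """KL divergence D(P||Q) in bits by trapezoidal integration.

    Both densities are re-evaluated on the union of their padded supports so
    no reference mass is discarded; q is floored at ``floor`` to keep the
    integrand finite where the model assigns (numerically) zero density.
    """
    if p.dim != q.dim:
        raise ValueError("densities have different dimensionality")
    dim = p.dim
    if grid_points is None:
        grid_points = 512 if dim == 1 else 128
    axes = []
    for d in range(dim):
        lo = min(p.axes[d][0], q.axes[d][0])
        hi = max(p.axes[d][-1], q.axes[d][-1])
        axes.append(np.linspace(lo, hi, grid_points))
    if dim == 1:
        pts = axes[0][None, :]
        shape = (grid_points,)
    else:
        gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.vstack([gx.ravel(), gy.ravel()])
        shape = gx.shape
    pd = p.kde(pts).reshape(shape)
    qd = np.maximum(q.kde(pts).reshape(shape), floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.where(pd > 0, pd * np.log2(pd / qd), 0.0)
    z = integrand
    for ax in reversed(axes):
        z = np.trapezoid(z, ax, axis=-1)
    return float(z)


def kl_from_samples(p_sample, q_sample, **kw) -> float:
    """KL divergence in bits between KDEs fitted to two samples."""
    return kl_divergence(estimate_pdf(p_sample), estimate_pdf(q_sample), **kw)


# ---------------------------------------------------------------------------
# Gini sparsity
# ---------------------------------------------------------------------------

def lorenz_curve(x: np.ndarray):
    """Discrete Lorenz curve: cumulative share of total response held by the
    lowest-responding fraction of units.  Returns (F, L) with F[0]=L[0]=0."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    cum = np.concatenate([[0.0], np.cumsum(x)])
    total = cum[-1]
    F = np.arange(n + 1) / n
    return F, cum / total


def gini(x) -> float:
    """Gini sparseness index Lambda = 1 - 2 * integral_0^1 L(F) dF.

    Requires elementwise non-negative input with positive sum.  0 for a
    uniform response vector; tends to 1 as a single unit dominates (the
    discrete Lorenz estimator gives (N-1)/N for a one-hot vector).
    Raises ``ValueError`` on negative entries or an all-zero vector.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty response vector")
    if np.any(x < 0):
        raise ValueError("gini requires non-negative responses "
                         "(take magnitudes of signed activities first)")
    if x.sum() <= 0:
        raise ValueError("all-zero response vector: sparsity undefined")
    F, L = lorenz_curve(x)
    return float(1.0 - 2.0 * np.trapezoid(L, F))


@dataclass
class SparsityResult:
    """Spatial and temporal Gini profiles of a stimulus x neuron response set.

    ``spatial[m]`` is the sparsity of the population response to stimulus m;
    ``temporal[n]`` is the sparsity of neuron n's response across stimuli.
    Undefined entries (all-zero rows/columns) are NaN.
    """

    spatial: np.ndarray
    temporal: np.ndarray

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.spatial).sum() + np.isnan(self.temporal).sum())


def sparsity_profile(responses: np.ndarray, signed: bool = True) -> SparsityResult:
    """Gini sparsity of an M stimuli x N neurons response matrix.

    Signed activities (linear model outputs) are converted to magnitudes
    first; spiking potentials are non-negative by construction.
    """
    R = np.asarray(responses, dtype=float)
    if R.ndim != 2 or min(R.shape) < 2:
        raise ValueError("need an M x N response matrix with M, N >= 2")
    if signed:
        R = np.abs(R)
    elif np.any(R < 0):
        raise ValueError("negative responses with signed=False")

    def safe(v):
        try:
            return gini(v)
        except ValueError:
            return np.nan

    spatial = np.array([safe(R[m]) for m in range(R.shape[0])])
    temporal = np.array([safe(R[:, n]) for n in range(R.shape[1])])
    return SparsityResult(spatial=spatial, temporal=temporal)
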
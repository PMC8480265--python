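"""Sparse-coding encoder on whitened patches.

The classical generative scheme: a patch x is modelled as x ~ A a with a
sparse coefficient vector a.  Inference minimises the energy

    E(a) = 1/2 ||x - A a||^2 + lam * sum_i S(a_i),      S(u) = log(1 + u^2)

by gradient descent; learning follows the reconstruction-error gradient on
A with a per-basis gain adaptation that equalises coefficient variances
across units.  Converged retinal receptive fields are recovered by the
linear-stability reverse-correlation formula

    xi = A [A^T A + lam * S''(0) I]^{-1},               S''(0) = 2

with lam = 0.14 * sigma, sigma^2 the variance of the input dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .synthetic import PatchSet


def prior_S(a: np.ndarray) -> np.ndarray:
    return np.log1p(a**2)


def prior_dS(a: np.ndarray) -> np.ndarray:
    return 2.0 * a / (1.0 + a**2)


PRIOR_S2_AT_0 = 2.0  # second derivative of log(1+x^2) at 0


class SCDivergence(RuntimeError):
    """Raised when coefficient inference diverges (energy keeps rising)."""


@dataclass
class SCModel:
    """Learned sparse-coding dictionary.

    ``A`` holds one basis function per column (pixels x n_units); ``lam`` is
    the sparsity weight used for coefficient inference and RF recovery
    (0.14 sigma, with sigma^2 the input variance); ``learn_lam`` is the
    stronger prior weight used while learning the dictionary, which keeps
    the coefficients in the sparsifying (non-quadratic) regime of the
    log(1+x^2) prior; ``gain`` is the adaptive per-basis norm used to
    equalise coefficient variances during learning.
    """

    A: np.ndarray
    lam: float
    learn_lam: float | None = None
    gain: np.ndarray | None = None
    input_variance: float = 1.0
    seed: int | None = None
    training_log: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.A.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.A.shape[0]

    @property
    def n_weights(self) -> int:
        """Total fitted weight count (pixels x units)."""
        return self.A.size


def sc_energy(model: SCModel, x: np.ndarray, a: np.ndarray) -> float:
    r = x - model.A @ a
    return float(0.5 * r @ r + model.lam * np.sum(prior_S(a)))


def sc_infer(model: SCModel, patch: np.ndarray, iters: int = 200,
             a0: np.ndarray | None = None) -> np.ndarray:
    """Infer sparse coefficients for one whitened patch by gradient descent.

    Step size is 1/L with L an upper bound on the energy curvature, so the
    energy is non-increasing; five consecutive energy increases raise
    ``SCDivergence``.
    """
    x = np.asarray(patch, dtype=float).ravel()
    if x.size != model.n_pixels:
        raise ValueError("patch length does not match basis rows")
    A = model.A
    a = np.zeros(model.n_units) if a0 is None else np.asarray(a0, dtype=float).copy()
    L = np.linalg.norm(A, 2) ** 2 + 2.0 * model.lam
    step = 1.0 / L
    e_prev = sc_energy(model, x, a)
    n_up = 0
    AtA = A.T @ A
    Atx = A.T @ x
    for _ in range(iters):
        grad = AtA @ a - Atx + model.lam * prior_dS(a)
        a -= step * grad
        e = sc_energy(model, x, a)
        if e > e_prev + 1e-12:
            n_up += 1
            if n_up >= 5:
                raise SCDivergence("sc_infer energy increased 5 consecutive steps")
        else:
            n_up = 0
        e_prev = e
    return a


def sc_infer_batch(model: SCModel, X: np.ndarray, iters: int = 100) -> np.ndarray:
    """Vectorised coefficient inference for rows of X; returns (n, n_units)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = model.A
    AtA = A.T @ A
    AtX = X @ A
    L = np.linalg.norm(A, 2) ** 2 + 2.0 * model.lam
    step = 1.0 / L
    coeffs = np.zeros((X.shape[0], model.n_units))
    for _ in range(iters):
        grad = coeffs @ AtA - AtX + model.lam * prior_dS(coeffs)
        coeffs -= step * grad
    return coeffs


def sc_learn(
    patches: PatchSet | np.ndarray,
    n_units: int = 225,
    epochs: int = 10,
    batch: int = 100,
    lr: float = 1.0,
    infer_iters: int = 100,
    lam: float | None = None,
    recon_lam: float | None = None,
    var_goal: float | None = None,
    seed: int | None = 0,
) -> SCModel:
    """Learn a sparse-coding dictionary by batched gradient descent.

    Each batch: infer coefficients, take a gradient step on the
    reconstruction error, then adapt per-basis gains so coefficient
    variances equalise.  The learning rate halves every quarter of training.
    Deterministic under ``seed`` (which only sets the initial basis; patches
    are consumed in stream order).
    """
    X = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    n, p = X.shape
    if n < 10 * n_units:
        warnings.warn("fewer than 10x more patches than units; dictionary may be poor")
    sigma2 = float(np.var(X))
    sigma = np.sqrt(sigma2)
    if lam is None:
        lam = 0.8 * sigma          # learning-phase prior weight
    if recon_lam is None:
        recon_lam = 0.14 * sigma   # reconstruction / RF-recovery weight
    if var_goal is None:
        var_goal = sigma2
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, n_units))
    A /= np.linalg.norm(A, axis=0, keepdims=True)
    gain = np.ones(n_units)
    a_var = np.full(n_units, var_goal)

    model = SCModel(A=A, lam=lam, learn_lam=lam, gain=gain,
                    input_variance=sigma2, seed=seed)
    n_batches = max(1, n // batch)
    total = epochs * n_batches
    log_resid = []
    step_lr = lr
    done = 0
    for ep in range(epochs):
        for b in range(n_batches):
            Xb = X[b * batch:(b + 1) * batch]
            C = sc_infer_batch(model, Xb, iters=infer_iters)   # (batch, units)
            R = Xb - C @ A.T                                    # residuals
            dA = (R.T @ C) / Xb.shape[0]
            A += step_lr * dA
            if not np.all(np.isfinite(A)):
                raise FloatingPointError(
                    f"NaN/inf in basis at epoch {ep}, batch {b} (lr={step_lr}, lam={lam})")
            # gain adaptation: equalise coefficient variances across units
            a_var = 0.99 * a_var + 0.01 * np.mean(C**2, axis=0)
            gain *= (a_var / var_goal) ** 0.02
            norms = np.linalg.norm(A, axis=0)
            norms[norms == 0] = 1.0
            A *= gain / norms
            log_resid.append(float(np.mean(R**2)))
            done += 1
            if total >= 4 and done % max(1, total // 4) == 0:
                step_lr *= 0.5
    model.A = A
    model.gain = gain
    model.lam = recon_lam
    model.training_log = {"mean_sq_residual": log_resid, "learn_lam": lam,
                          "recon_lam": recon_lam, "epochs": epochs, "batch": batch}
    return model


def sc_recover_rfs(model: SCModel, lam: float | None = None) -> np.ndarray:
    """Retinal RFs xi = A [A^T A + lam S''(0) I]^{-1}; one column per unit."""
    lam = model.lam if lam is None else lam
    n = model.n_units
    M = model.A.T @ model.A + lam * PRIOR_S2_AT_0 * np.eye(n)
    try:
        xi = model.A @ np.linalg.inv(M)
    except np.linalg.LinAlgError as e:
        raise FloatingPointError(
            "singular normal matrix in RF recovery; consider a lambda floor") from e
    return xi


def sc_rf_maps(model: SCModel, patch_px: int) -> np.ndarray:
    """Recovered RFs reshaped to (n_units, patch_px, patch_px)."""
    xi = sc_recover_rfs(model)
    return xi.T.reshape(model.n_units, patch_px, patch_px)
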
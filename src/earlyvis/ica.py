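"""ICA encoder on PCA-reduced patches.

The pipeline is: centre patches, project onto the top d principal
components (L = U~^T X_C), variance-normalise the projection, then estimate
a square un-mixing matrix W by fixed-point negentropy maximisation
(fastICA with symmetric orthogonalisation).  V1 activity is Sigma = W L and
retinal receptive fields are recovered as xi = U~ W^T + <X>.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .frontend import PCATransform, fit_pca
from .synthetic import PatchSet


@dataclass
class ICAModel:
    """Fitted ICA encoder.

    ``W`` maps the PCA projection L directly to unit activities
    (Sigma = W L); it folds in the variance normalisation applied before
    the fixed-point iteration, so ``W_white`` (rows orthonormal in the
    whitened space) is kept separately for diagnostics.
    """

    W: np.ndarray
    W_white: np.ndarray
    pca: PCATransform
    scale: np.ndarray              # per-component std used for whitening L
    converged: bool = True
    n_iter: int = 0
    contrast: str = "logcosh"
    seed: int | None = None

    @property
    def n_units(self) -> int:
        return self.W.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.pca.components.shape[0]

    @property
    def n_weights(self) -> int:
        """Fitted retinal-filter weight count (units x pixels)."""
        return self.n_units * self.n_pixels


def ica_fit(
    L: np.ndarray,
    pca: PCATransform,
    n_units: int | None = None,
    contrast: str = "logcosh",
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int | None = 0,
) -> ICAModel:
    """Estimate the un-mixing matrix from the PCA projection L (d x n).

    Components of L are variance-normalised, then fastICA with symmetric
    (parallel) orthogonalisation and a smooth even contrast maximises
    negentropy.  Non-convergence at ``max_iter`` is flagged on the returned
    model, not raised.
    """
    L = np.asarray(L, dtype=float)
    d, n = L.shape
    if n_units is None:
        n_units = d
    if n_units != d:
        raise ValueError("square ICA: n_units must equal the PCA dimension")
    scale = L.std(axis=1)
    scale[scale == 0] = 1.0
    Lw = L / scale[:, None]

    ica = FastICA(n_components=d, algorithm="parallel", whiten=False,
                  fun=contrast, tol=tol, max_iter=max_iter, random_state=seed)
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ica.fit(Lw.T)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    W_white = ica.components_
    # unit-norm rows in the whitened space (symmetric orthogonalisation
    # leaves them orthonormal up to scaling)
    W_white = W_white / np.linalg.norm(W_white, axis=1, keepdims=True)
    W = W_white / scale[None, :]
    return ICAModel(W=W, W_white=W_white, pca=pca, scale=scale,
                    converged=converged, n_iter=int(ica.n_iter_),
                    contrast=contrast, seed=seed)


def ica_fit_patches(patches: PatchSet | np.ndarray, d: int = 150, **kw) -> ICAModel:
    """Convenience: fit PCA then ICA directly from a patch matrix."""
    pca = fit_pca(patches, d=d)
    X = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    return ica_fit(pca.project(X), pca, **kw)


def ica_activity(model: ICAModel, patches: np.ndarray) -> np.ndarray:
    """Unit activities Sigma = W U~^T (X - <X>), one row per unit."""
    X = np.atleast_2d(np.asarray(patches, dtype=float))
    if X.shape[1] != model.n_pixels:
        raise ValueError("patch length does not match PCA basis")
    return model.W @ model.pca.project(X)


def ica_recover_rfs(model: ICAModel, add_mean: bool = True) -> np.ndarray:
    """Retinal RFs xi = U~ W^T + <X>, one column per unit.

    Each RF is sign-flipped so its maximum-absolute pixel is positive
    (display and fit stability; ICA components have arbitrary sign).
    """
    xi = model.pca.components @ model.W.T
    peak = xi[np.argmax(np.abs(xi), axis=0), np.arange(xi.shape[1])]
    xi = xi * np.where(peak >= 0, 1.0, -1.0)
    if add_mean:
        xi = xi + model.pca.mean[:, None]
    return xi


def ica_rf_maps(model: ICAModel, patch_px: int, add_mean: bool = False) -> np.ndarray:
    """Recovered RFs as (n_units, patch_px, patch_px) maps.

    The patch mean is omitted by default: for shape characterisation the
    informative structure is the filter itself, and with standardised
    synthetic patches the mean is ~0 anyway.
    """
    xi = ica_recover_rfs(model, add_mean=add_mean)
    return xi.T.reshape(model.n_units, patch_px, patch_px)
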
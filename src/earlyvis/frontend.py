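"""LGN-stage pre-processing for the three encoding models.

Three alternative front ends stand between the retinal patch and the V1
layer:

* a zero-phase whitening filter ``H(f) = f * exp(-(f/f0)^4)`` with cut-off
  ``f0 = 10`` cycles/deg, applied in the frequency domain (sparse coding);
* truncated PCA decorrelation of centred patches (ICA);
* half-rectified ON/OFF difference-of-Gaussians filtering followed by a
  rank-order first-spike latency code (STDP): responses r are converted to
  latencies 1/r and only the earliest fraction (10% by default) of spikes
  propagates to cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

from .synthetic import ImageSet, PatchSet


# ---------------------------------------------------------------------------
# whitening (sparse-coding front end)
# ---------------------------------------------------------------------------

def whitening_gain(f: np.ndarray, f0: float = 10.0) -> np.ndarray:
    """Radial gain of the whitening filter, f * exp(-(f/f0)^4)."""
    f = np.asarray(f, dtype=float)
    return f * np.exp(-((f / f0) ** 4))


def whiten_image(image: np.ndarray, px_per_deg: float, f0: float = 10.0) -> np.ndarray:
    """Apply the zero-phase whitening filter in the frequency domain.

    The gain rises linearly with radial frequency (decorrelating the 1/f
    spectrum of natural input) and is trimmed beyond the cut-off ``f0``.
    The DC component is exactly zero on output.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("whiten_image expects a square 2-D image")
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    n = image.shape[0]
    fx = np.fft.fftfreq(n, d=1.0 / px_per_deg)
    fr = np.hypot(*np.meshgrid(fx, fx))
    out = np.fft.ifft2(np.fft.fft2(image) * whitening_gain(fr, f0)).real
    return out


def whiten_imageset(images: ImageSet, f0: float = 10.0) -> ImageSet:
    return ImageSet(
        images=[whiten_image(im, images.px_per_deg, f0) for im in images.images],
        px_per_deg=images.px_per_deg,
        field_deg=images.field_deg,
    )


# ---------------------------------------------------------------------------
# truncated PCA (ICA front end)
# ---------------------------------------------------------------------------

@dataclass
class PCATransform:
    """Truncated PCA of centred patches: L = U~^T (X - <X>).

    ``components`` is the pixels x d matrix U~ with orthonormal columns in
    descending eigenvalue order.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    @property
    def d(self) -> int:
        return self.components.shape[1]

    def project(self, patches: np.ndarray) -> np.ndarray:
        """Project flattened patches (rows) to L with shape (d, n_patches)."""
        return self.components.T @ (np.asarray(patches) - self.mean).T

    def back_project(self, L: np.ndarray) -> np.ndarray:
        """Reconstruct patches (rows) from projections (d, n)."""
        return (self.components @ L).T + self.mean


def fit_pca(patches: PatchSet | np.ndarray, d: int = 150) -> PCATransform:
    """Top-``d`` principal components of the centred patch matrix."""
    X = patches.patches if isinstance(patches, PatchSet) else np.asarray(patches)
    n, p = X.shape
    if d > p:
        raise ValueError(f"d={d} exceeds pixel count {p}")
    if n <= d:
        raise ValueError("need more patches than components")
    pca = PCA(n_components=d, svd_solver="full" if d == p else "auto")
    pca.fit(X)
    return PCATransform(
        mean=pca.mean_,
        components=pca.components_.T,
        explained_variance=pca.explained_variance_,
    )


# ---------------------------------------------------------------------------
# DoG ON/OFF bank + latency code (STDP front end)
# ---------------------------------------------------------------------------

def dog_kernel(px_per_deg: float, sigma_c_deg: float = 0.2, surround_ratio: float = 3.0,
               support_sigmas: float = 3.0) -> np.ndarray:
    """Centre-surround difference-of-Gaussians kernel.

    Balanced to zero sum (so constant input elicits no response) and scaled
    to unit L2 norm.  Default centre sigma 0.2 deg (one pixel at 5 px/deg)
    with the conventional 1:3 centre-to-surround ratio.
    """
    sc = sigma_c_deg * px_per_deg
    ss = surround_ratio * sc
    half = int(np.ceil(support_sigmas * ss))
    ax = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx**2 + yy**2
    g = np.exp(-r2 / (2 * sc**2)) / (2 * np.pi * sc**2) - np.exp(-r2 / (2 * ss**2)) / (2 * np.pi * ss**2)
    g -= g.mean()
    return g / np.linalg.norm(g)


@dataclass
class LGNBank:
    """One ON and one OFF centre-surround afferent per patch pixel.

    In ``merged`` mode the two polarities at a pixel are collapsed into a
    single afferent carrying the dominant polarity's (rectified) response,
    halving the afferent count; ``split`` keeps them separate.
    """

    kernel: np.ndarray
    patch_px: int
    px_per_deg: float
    mode: Literal["merged", "split"] = "merged"

    @property
    def n_pixels(self) -> int:
        return self.patch_px * self.patch_px

    @property
    def n_afferents(self) -> int:
        return self.n_pixels if self.mode == "merged" else 2 * self.n_pixels

    def filter_patch(self, patch: np.ndarray):
        """Half-rectified ON and OFF response maps for one patch."""
        r = self.signed_response(patch)
        return np.maximum(r, 0.0), np.maximum(-r, 0.0)

    def signed_response(self, patch: np.ndarray) -> np.ndarray:
        patch = np.asarray(patch, dtype=float)
        if patch.ndim == 1:
            patch = patch.reshape(self.patch_px, self.patch_px)
        if min(patch.shape) < 1:
            raise ValueError("empty patch")
        # symmetric padding keeps the centre-surround balance at the patch
        # border, so constant input elicits exactly zero response everywhere
        half = self.kernel.shape[0] // 2
        padded = np.pad(patch, half, mode="symmetric")
        return signal.fftconvolve(padded, self.kernel[::-1, ::-1], mode="valid")

    def afferent_responses(self, patch: np.ndarray):
        """Flat non-negative afferent drive, plus the signed map.

        merged: (n_pixels,) = |DoG response| per pixel.
        split:  (2*n_pixels,) = [ON map, OFF map] concatenated.
        """
        r = self.signed_response(patch)
        if self.mode == "merged":
            return np.abs(r).ravel(), r
        return np.concatenate([np.maximum(r, 0.0).ravel(), np.maximum(-r, 0.0).ravel()]), r

    def reconstruct_rf(self, weights: np.ndarray, signs: np.ndarray | None = None) -> np.ndarray:
        """Retinal-space RF as the weight-blended sum of afferent kernels.

        split mode: RF = conv(w_ON - w_OFF, K); merged mode needs per-afferent
        polarity ``signs`` (which polarity the afferent predominantly
        signalled for this neuron): RF = conv(w * sign, K).
        """
        k = self.patch_px
        if self.mode == "split":
            wmap = (weights[:self.n_pixels] - weights[self.n_pixels:]).reshape(k, k)
        else:
            if signs is None:
                raise ValueError("merged-polarity RF recovery needs per-afferent signs")
            wmap = (weights * signs).reshape(k, k)
        return signal.fftconvolve(wmap, self.kernel, mode="same")


def build_lgn_bank(patch_px: int = 15, px_per_deg: float = 5.0,
                   sigma_c_deg: float = 0.2, surround_ratio: float = 3.0,
                   mode: Literal["merged", "split"] = "merged") -> LGNBank:
    return LGNBank(kernel=dog_kernel(px_per_deg, sigma_c_deg, surround_ratio),
                   patch_px=patch_px, px_per_deg=px_per_deg, mode=mode)


def dog_filter_patch(patch: np.ndarray, bank: LGNBank):
    """Half-rectified ON and OFF maps; at each pixel at most one is nonzero."""
    return bank.filter_patch(patch)


@dataclass
class SpikeList:
    """Ranked first-spike latencies of the afferents for one patch.

    ``order`` lists the propagated afferent ids by ascending latency
    (earliest first); silent afferents never propagate.  ``signed_map``
    optionally carries the signed DoG response map used to derive polarity.
    """

    latencies: np.ndarray          # per afferent; inf where silent
    order: np.ndarray              # propagated afferent ids, earliest first
    n_afferents: int
    signed_map: np.ndarray | None = None

    @property
    def propagated(self) -> np.ndarray:
        mask = np.zeros(self.n_afferents, dtype=bool)
        mask[self.order] = True
        return mask

    @property
    def empty(self) -> bool:
        return self.order.size == 0


def latency_encode(responses: np.ndarray, top_fraction: float = 0.1) -> SpikeList:
    """Convert non-negative afferent responses to a rank-order spike list.

    Latency is 1/r for r > 0 (any monotonically decreasing map gives the
    same ranks).  Exactly the earliest ceil(top_fraction * n_afferents)
    spikes propagate, fewer if not enough afferents respond; ties are broken
    by afferent index.  An all-zero input yields an empty (flagged, not
    raised) propagated set.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    r = np.asarray(responses, dtype=float).ravel()
    if np.any(r < 0):
        raise ValueError("responses must be non-negative")
    n = r.size
    lat = np.full(n, np.inf)
    active = r > 0
    lat[active] = 1.0 / r[active]
    n_prop = int(np.ceil(top_fraction * n))
    # stable sort -> ties broken by afferent index
    order = np.argsort(lat, kind="stable")
    order = order[:n_prop]
    order = order[np.isfinite(lat[order])]
    return SpikeList(latencies=lat, order=order, n_afferents=n)


def encode_patch(patch: np.ndarray, bank: LGNBank, top_fraction: float = 0.1) -> SpikeList:
    """DoG-filter a patch and latency-encode the afferent responses."""
    resp, signed = bank.afferent_responses(patch)
    sl = latency_encode(resp, top_fraction)
    sl.signed_map = signed
    return sl


# ---------------------------------------------------------------------------
# image loading
# ---------------------------------------------------------------------------

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def load_image_dir(path: str | Path, px_per_deg: float = 5.0,
                   field_deg: float | None = None,
                   native_px_per_deg: float | None = None,
                   standardize: bool = True) -> ImageSet:
    """Load a directory of PNG/TIFF images as a grayscale ImageSet.

    RGB images are converted with standard luminance weights and resized to
    the target sampling density by bilinear interpolation when the native
    density is given.  Each image is standardised to zero mean, unit
    variance unless ``standardize=False``.
    """
    from PIL import Image

    path = Path(path)
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in {".png", ".tif", ".tiff"})
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF images under {path}")
    images = []
    for p in files:
        arr = np.asarray(Image.open(p), dtype=float)
        if arr.ndim == 3:
            arr = arr[..., :3] @ _LUMA
        if native_px_per_deg is not None and native_px_per_deg != px_per_deg:
            scale = px_per_deg / native_px_per_deg
            new = (max(1, int(round(arr.shape[1] * scale))), max(1, int(round(arr.shape[0] * scale))))
            arr = np.asarray(Image.fromarray(arr).resize(new, Image.BILINEAR), dtype=float)
        if standardize:
            arr = arr - arr.mean()
            sd = arr.std()
            if sd > 0:
                arr = arr / sd
        images.append(arr)
    if field_deg is None:
        field_deg = images[0].shape[0] / px_per_deg
    return ImageSet(images=images, px_per_deg=px_per_deg, field_deg=field_deg)
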
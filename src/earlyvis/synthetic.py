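"""Synthetic inputs for the encoding pipeline.

Everything the models consume can be generated here with no downloads:

* naturalistic grayscale images with a 1/f amplitude spectrum (the standard
  second-order statistic of natural scenes), at the study geometry of a
  20 deg x 20 deg field sampled at 5 px/deg;
* ground-truth Gabor receptive fields for round-trip tests of the fitter;
* surrogate reference tables of receptive-field shape (FSV pairs) and
  orientation-tuning bandwidth, standing in for single-cell recordings in
  macaque V1;
* parametric orientation-tuned populations with closed-form Fisher
  information, used as oracles for the information estimators.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .gabor import GaborParams, gabor_patch


# ---------------------------------------------------------------------------
# image and patch containers
# ---------------------------------------------------------------------------

@dataclass
class ImageSet:
    """A homogeneous collection of grayscale images with retinal geometry."""

    images: list[np.ndarray]
    px_per_deg: float
    field_deg: float

    def __post_init__(self):
        if self.px_per_deg <= 0:
            raise ValueError("px_per_deg must be positive")
        shapes = {im.shape for im in self.images}
        if len(shapes) > 1:
            raise ValueError("all images must share one shape")


@dataclass
class PatchSet:
    """Flattened square patches sampled from an ImageSet.

    ``patches`` has one row per patch of length (patch_deg*px_per_deg)^2;
    ``source_coords`` records (image index, top row, left col) per patch.
    """

    patches: np.ndarray
    patch_deg: float
    px_per_deg: float
    source_coords: np.ndarray
    seed: int | None = None

    @property
    def patch_px(self) -> int:
        return int(round(self.patch_deg * self.px_per_deg))

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    def as_images(self) -> np.ndarray:
        k = self.patch_px
        return self.patches.reshape(-1, k, k)

    @property
    def pixel_variance(self) -> float:
        """Pooled pixel variance of the sampled patches (the input variance
        sigma^2 used to scale the sparse-coding regulariser)."""
        return float(np.var(self.patches))


def gen_pink_noise_images(
    n: int,
    field_deg: float = 20.0,
    px_per_deg: float = 5.0,
    exponent: float = 1.0,
    seed: int | None = None,
) -> ImageSet:
    """Random-phase images with amplitude spectrum proportional to 1/f^exponent.

    Each image is standardised to zero mean and unit variance.  ``exponent=0``
    gives white noise; ``exponent=1`` reproduces the canonical natural-scene
    amplitude falloff.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    npx = int(round(field_deg * px_per_deg))
    if npx <= 0:
        raise ValueError("non-positive image size")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(npx, d=1.0 / px_per_deg)
    fx = np.fft.fftfreq(npx, d=1.0 / px_per_deg)
    fr = np.hypot(*np.meshgrid(fx, fy))
    with np.errstate(divide="ignore"):
        amp = np.where(fr > 0, fr ** (-exponent), 0.0)
    images = []
    for _ in range(n):
        white = rng.standard_normal((npx, npx))
        spec = np.fft.fft2(white) * amp
        im = np.fft.ifft2(spec).real
        im -= im.mean()
        sd = im.std()
        if sd > 0:
            im /= sd
        images.append(im)
    return ImageSet(images=images, px_per_deg=px_per_deg, field_deg=field_deg)


def gen_natural_surrogate_images(
    n: int,
    field_deg: float = 20.0,
    px_per_deg: float = 5.0,
    exponent: float = 1.0,
    components_per_sqdeg: float = 0.5,
    background_weight: float = 0.35,
    seed: int | None = None,
) -> ImageSet:
    """Naturalistic surrogate with both 1/f spectrum and sparse structure.

    Real scenes are not Gaussian: on top of the 1/f amplitude falloff they
    contain sparse, localised oriented structure (edges, contours), which is
    what drives generative encoders towards localised oriented filters.
    This surrogate superimposes a sparse set of random Gabor components
    (Laplacian-distributed amplitudes, random position / orientation /
    frequency / phase) on a 1/f background.  The pure 1/f generator
    ``gen_pink_noise_images`` remains available for second-order-only
    surrogates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    npx = int(round(field_deg * px_per_deg))
    rng = np.random.default_rng(seed)
    background = gen_pink_noise_images(n, field_deg, px_per_deg, exponent,
                                       seed=rng.integers(2**31 - 1))
    n_comp = max(1, int(round(components_per_sqdeg * field_deg * field_deg)))
    x = (np.arange(npx) - (npx - 1) / 2.0) / px_per_deg
    xx, yy = np.meshgrid(x, x)
    half = field_deg / 2.0
    images = []
    for b in background.images:
        im = background_weight * b
        for _ in range(n_comp):
            f = rng.uniform(0.4, 2.0)
            th = rng.uniform(0.0, np.pi)
            sx = rng.uniform(0.25, 0.6) / f
            sy = sx * rng.uniform(1.0, 3.0)
            x0 = rng.uniform(-half, half)
            y0 = rng.uniform(-half, half)
            amp = rng.laplace(0.0, 1.0)
            ct, st = np.cos(th), np.sin(th)
            xr = (xx - x0) * ct + (yy - y0) * st
            yr = -(xx - x0) * st + (yy - y0) * ct
            env = np.exp(-(xr**2) / (2 * sx**2) - (yr**2) / (2 * sy**2))
            im = im + amp * env * np.cos(2 * np.pi * f * xr - rng.uniform(0, 2 * np.pi))
        im -= im.mean()
        sd = im.std()
        if sd > 0:
            im /= sd
        images.append(im)
    return ImageSet(images=images, px_per_deg=px_per_deg, field_deg=field_deg)


def radial_amplitude_spectrum(image: np.ndarray, px_per_deg: float, n_bins: int = 20):
    """Radially averaged amplitude spectrum; returns (freq centres, amplitude)."""
    npx = image.shape[0]
    spec = np.abs(np.fft.fft2(image - image.mean()))
    fy = np.fft.fftfreq(npx, d=1.0 / px_per_deg)
    fx = np.fft.fftfreq(image.shape[1], d=1.0 / px_per_deg)
    fr = np.hypot(*np.meshgrid(fx, fy)).ravel()
    a = spec.ravel()
    mask = fr > 0
    fr, a = fr[mask], a[mask]
    edges = np.logspace(np.log10(fr.min()), np.log10(fr.max()), n_bins + 1)
    idx = np.clip(np.digitize(fr, edges) - 1, 0, n_bins - 1)
    freq = np.zeros(n_bins)
    amp = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            freq[b] = fr[sel].mean()
            amp[b] = a[sel].mean()
    ok = amp > 0
    return freq[ok], amp[ok]


def spectral_slope(image: np.ndarray, px_per_deg: float) -> float:
    """Log-log regression slope of the radial amplitude spectrum."""
    f, a = radial_amplitude_spectrum(image, px_per_deg)
    coef = np.polyfit(np.log10(f), np.log10(a), 1)
    return float(coef[0])


def sample_patches(
    images: ImageSet,
    n_patches: int,
    patch_deg: float = 3.0,
    seed: int | None = None,
) -> PatchSet:
    """Sample square patches uniformly at random (with replacement, overlap
    allowed) from the images."""
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    k = int(round(patch_deg * images.px_per_deg))
    h, w = images.images[0].shape
    if k > h or k > w:
        raise ValueError("patch larger than image")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(images.images), size=n_patches)
    rows = rng.integers(0, h - k + 1, size=n_patches)
    cols = rng.integers(0, w - k + 1, size=n_patches)
    stack = np.asarray(images.images)
    patches = np.empty((n_patches, k * k))
    for j in range(n_patches):
        patches[j] = stack[idx[j], rows[j]:rows[j] + k, cols[j]:cols[j] + k].ravel()
    coords = np.stack([idx, rows, cols], axis=1)
    return PatchSet(patches=patches, patch_deg=patch_deg, px_per_deg=images.px_per_deg,
                    source_coords=coords, seed=seed)


# ---------------------------------------------------------------------------
# ground-truth receptive fields
# ---------------------------------------------------------------------------

def gen_gabor_rf(
    params: GaborParams,
    patch_px: int = 15,
    px_per_deg: float = 5.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render a ground-truth Gabor RF on the patch grid, plus optional
    i.i.d. Gaussian pixel noise."""
    rf = gabor_patch(params, (patch_px, patch_px), px_per_deg)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rf = rf + rng.normal(0.0, noise_sd, size=rf.shape)
    return rf


def random_gabor_params(rng: np.random.Generator, patch_deg: float = 3.0) -> GaborParams:
    """Draw plausible simple-cell Gabor parameters well inside the patch."""
    f = rng.uniform(0.5, 1.8)
    return GaborParams(
        x0=rng.uniform(-0.25, 0.25) * patch_deg / 3.0,
        y0=rng.uniform(-0.25, 0.25) * patch_deg / 3.0,
        theta_deg=rng.uniform(0.0, 180.0),
        freq=f,
        phase_deg=rng.uniform(-180.0, 180.0),
        sigma_x=rng.uniform(0.25, 0.55) / f,
        sigma_y=rng.uniform(0.25, 0.8) / f,
        amplitude=1.0,
        offset=0.0,
    )


# ---------------------------------------------------------------------------
# surrogate reference tables (stand-ins for macaque single-cell data)
# ---------------------------------------------------------------------------

@dataclass
class ReferenceSample:
    """A tabular sample of physiological parameters.

    Synthetic samples are drawn from a documented Gaussian mixture truncated
    to positive values; external tables loaded from file carry provenance
    ``"external-file"``.
    """

    variables: list[str]
    values: np.ndarray            # (n, n_vars)
    provenance: str = "synthetic"
    dist_params: dict | None = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] < 2:
            raise ValueError("reference sample needs n >= 2 rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reference sample must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variables.index(name)]


# Default mixtures emulating published macaque V1 summaries: FSVs concentrate
# in the low (n_x, n_y) square with a tail of elongated / multi-lobed cells,
# and the tuning-bandwidth distribution peaks near 19 deg with a broad tail.
_FSV_MIXTURE = {
    "weights": [0.62, 0.38],
    "means": [[0.33, 0.30], [0.62, 0.78]],
    "covs": [
        [[0.012, 0.003], [0.003, 0.012]],
        [[0.05, 0.01], [0.01, 0.09]],
    ],
}
_BANDWIDTH_MIXTURE = {
    "weights": [0.75, 0.25],
    "means": [[19.0], [38.0]],
    "covs": [[[36.0]], [[144.0]]],
}


def gen_reference_sample(
    kind: Literal["fsv", "bandwidth"],
    n: int,
    dist_params: dict | None = None,
    seed: int | None = None,
) -> ReferenceSample:
    """Draw a surrogate reference table from a truncated Gaussian mixture.

    ``kind="fsv"`` yields (n_x, n_y) pairs; ``kind="bandwidth"`` yields
    half-width-at-half-height tuning bandwidths in degrees.  Draws with any
    non-positive coordinate are rejected and redrawn, so the sample lives in
    the positive orthant.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if kind == "fsv":
        params = dist_params or _FSV_MIXTURE
        names = ["n_x", "n_y"]
    elif kind == "bandwidth":
        params = dist_params or _BANDWIDTH_MIXTURE
        names = ["bandwidth_deg"]
    else:
        raise ValueError(f"unknown reference kind {kind!r}")
    rng = np.random.default_rng(seed)
    weights = np.asarray(params["weights"], dtype=float)
    weights = weights / weights.sum()
    means = [np.atleast_1d(m) for m in params["means"]]
    covs = [np.atleast_2d(c) for c in params["covs"]]
    dim = means[0].size
    out = np.empty((n, dim))
    filled = 0
    while filled < n:
        m = n - filled
        comp = rng.choice(len(weights), size=m, p=weights)
        draws = np.empty((m, dim))
        for c in range(len(weights)):
            sel = comp == c
            if sel.any():
                draws[sel] = rng.multivariate_normal(means[c], covs[c], size=int(sel.sum()))
        ok = np.all(draws > 0, axis=1)
        k = int(ok.sum())
        out[filled:filled + k] = draws[ok]
        filled += k
    return ReferenceSample(variables=names, values=out, provenance="synthetic",
                           dist_params=params)


# ---------------------------------------------------------------------------
# parametric tuned populations (Fisher-information oracle)
# ---------------------------------------------------------------------------

@dataclass
class TunedPopulation:
    """Independent orientation-tuned units with analytic tuning curves.

    Tuning is cosine-shaped on the orientation circle (period 180 deg):
    ``f_i(theta) = base_i + amp_i * cos(2 (theta - pref_i))`` in radians, or
    von Mises when ``kappa`` is set:
    ``f_i = base_i + amp_i * exp(kappa (cos 2(theta-pref_i) - 1))``.
    Responses are Poisson counts or Gaussian perturbations of the rate, so
    the population Fisher information has the closed form
    ``J(theta) = sum_i f_i'(theta)^2 / f_i(theta)`` (Poisson) or
    ``sum_i f_i'(theta)^2 / sigma^2`` (Gaussian).
    """

    base: np.ndarray
    amp: np.ndarray
    pref_deg: np.ndarray
    noise: Literal["poisson", "gaussian"] = "poisson"
    gaussian_sd: float = 1.0
    kappa: float | None = None
    seed: int | None = None

    def __post_init__(self):
        self.base = np.atleast_1d(np.asarray(self.base, dtype=float))
        self.amp = np.atleast_1d(np.asarray(self.amp, dtype=float))
        self.pref_deg = np.atleast_1d(np.asarray(self.pref_deg, dtype=float))
        if self.noise == "poisson" and np.any(self.base - np.abs(self.amp) <= 0):
            raise ValueError("poisson rates must stay positive: require base > |amp|")
        self._rng = np.random.default_rng(self.seed)

    @property
    def n_units(self) -> int:
        return self.base.size

    def rates(self, theta_deg: float) -> np.ndarray:
        d = 2.0 * np.deg2rad(theta_deg - self.pref_deg)
        if self.kappa is None:
            return self.base + self.amp * np.cos(d)
        return self.base + self.amp * np.exp(self.kappa * (np.cos(d) - 1.0))

    def drates(self, theta_deg: float) -> np.ndarray:
        """d f / d theta with theta in radians (the FI convention here)."""
        d = 2.0 * np.deg2rad(theta_deg - self.pref_deg)
        if self.kappa is None:
            return -2.0 * self.amp * np.sin(d)
        return (self.base * 0.0
                - 2.0 * self.kappa * self.amp * np.sin(d)
                * np.exp(self.kappa * (np.cos(d) - 1.0)))

    def closed_form_fi(self, theta_deg: float) -> float:
        """Population Fisher information at ``theta`` (radian parametrisation)."""
        fp = self.drates(theta_deg)
        if self.noise == "poisson":
            return float(np.sum(fp**2 / self.rates(theta_deg)))
        return float(np.sum(fp**2) / self.gaussian_sd**2)

    def sample(self, theta_deg: float, n: int = 1) -> np.ndarray:
        """Draw ``n`` response vectors at orientation ``theta`` (shape n x units)."""
        r = self.rates(theta_deg)
        if self.noise == "poisson":
            return self._rng.poisson(r, size=(n, self.n_units)).astype(float)
        return r + self._rng.normal(0.0, self.gaussian_sd, size=(n, self.n_units))


def gen_tuned_population(
    n_units: int,
    base: float | Sequence[float] = 10.0,
    amp: float | Sequence[float] = 8.0,
    pref_deg: Sequence[float] | None = None,
    noise: Literal["poisson", "gaussian"] = "poisson",
    gaussian_sd: float = 1.0,
    kappa: float | None = None,
    seed: int | None = None,
) -> TunedPopulation:
    """Build a TunedPopulation with evenly spaced preferred orientations."""
    if pref_deg is None:
        pref_deg = np.arange(n_units) * 180.0 / n_units
    base = np.broadcast_to(np.atleast_1d(base), (n_units,)).copy()
    amp = np.broadcast_to(np.atleast_1d(amp), (n_units,)).copy()
    return TunedPopulation(base=base, amp=amp, pref_deg=np.asarray(pref_deg, dtype=float),
                           noise=noise, gaussian_sd=gaussian_sd, kappa=kappa, seed=seed)
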
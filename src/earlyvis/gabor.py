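"""2-D Gabor fitting of receptive fields and frequency-normalised spread vectors.

A simple-cell receptive field is modelled as

    g(x, y) = A * exp(-xr^2 / (2 sx^2) - yr^2 / (2 sy^2))
                * cos(2 pi f xr - phi) + c

where (xr, yr) are coordinates rotated by the orientation ``theta`` so that
``xr`` points along the direction of carrier propagation (perpendicular to
the stripes).  ``sx`` is therefore the envelope spread along the carrier and
``sy`` the spread along the stripes (elongation).

The frequency-normalised spread vector (FSV) of a fit is ``[n_x, n_y] =
[sx, sy] * f``:  ``n_x`` tracks the number of lobes in the RF and ``n_y`` its
elongation, and the pair is invariant under translation, rotation and
isotropic rescaling of the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize


@dataclass
class GaborParams:
    """Ground-truth Gabor parameters (degrees of visual angle for lengths)."""

    x0: float = 0.0
    y0: float = 0.0
    theta_deg: float = 0.0
    freq: float = 1.0           # carrier frequency, cycles/deg
    phase_deg: float = 0.0
    sigma_x: float = 0.3        # envelope spread along carrier propagation, deg
    sigma_y: float = 0.3        # envelope spread along stripes, deg
    amplitude: float = 1.0
    offset: float = 0.0


@dataclass
class GaborFit:
    """Result of a nonlinear least-squares Gabor fit to an RF map."""

    params: GaborParams
    r2: float
    ss_res: float
    success: bool
    n_restarts: int = 1

    @property
    def freq(self) -> float:
        return self.params.freq


def patch_grid(shape: tuple[int, int], px_per_deg: float):
    """Pixel-centre coordinates in degrees, origin at the patch centre.

    Rows map to y (increasing downwards in array order but treated as a
    plain Euclidean axis here; all analyses are invariant to this choice).
    """
    ny, nx = shape
    x = (np.arange(nx) - (nx - 1) / 2.0) / px_per_deg
    y = (np.arange(ny) - (ny - 1) / 2.0) / px_per_deg
    return np.meshgrid(x, y)


def gabor_patch(params: GaborParams, shape: tuple[int, int], px_per_deg: float) -> np.ndarray:
    """Evaluate a 2-D Gabor on a pixel grid of ``shape`` at ``px_per_deg``."""
    if params.sigma_x <= 0 or params.sigma_y <= 0:
        raise ValueError("sigma_x and sigma_y must be positive")
    if params.freq < 0:
        raise ValueError("carrier frequency must be non-negative")
    xx, yy = patch_grid(shape, px_per_deg)
    return _gabor_eval(
        xx,
        yy,
        params.x0,
        params.y0,
        np.deg2rad(params.theta_deg),
        params.freq,
        np.deg2rad(params.phase_deg),
        params.sigma_x,
        params.sigma_y,
        params.amplitude,
        params.offset,
    )


def _gabor_eval(xx, yy, x0, y0, theta, f, phi, sx, sy, amp, off):
    ct, st = np.cos(theta), np.sin(theta)
    xr = (xx - x0) * ct + (yy - y0) * st
    yr = -(xx - x0) * st + (yy - y0) * ct
    env = np.exp(-(xr**2) / (2 * sx**2) - (yr**2) / (2 * sy**2))
    return amp * env * np.cos(2 * np.pi * f * xr - phi) + off


def _spectral_init(rf: np.ndarray, px_per_deg: float):
    """Initial carrier frequency and orientation from the FFT peak."""
    n = rf.shape[0]
    win = np.hanning(n)
    spec = np.abs(np.fft.fft2((rf - rf.mean()) * np.outer(win, win)))
    fy = np.fft.fftfreq(rf.shape[0], d=1.0 / px_per_deg)
    fx = np.fft.fftfreq(rf.shape[1], d=1.0 / px_per_deg)
    fxx, fyy = np.meshgrid(fx, fy)
    fr = np.hypot(fxx, fyy)
    spec = np.where(fr > 1e-9, spec, 0.0)  # ignore DC
    iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
    f0 = fr[iy, ix]
    theta0 = np.rad2deg(np.arctan2(fyy[iy, ix], fxx[iy, ix])) % 180.0
    return max(f0, 1e-3), theta0


def fit_gabor(
    rf: np.ndarray,
    px_per_deg: float,
    restarts: int = 4,
    seed: int | None = 0,
) -> GaborFit:
    """Fit a 2-D Gabor to an RF map by nonlinear least squares.

    Initialisation uses the spectral peak (carrier frequency and
    orientation) and the energy centroid (centre); the best of ``restarts``
    jittered starts by residual sum of squares is returned.  ``r2`` is
    ``1 - SS_res / SS_tot`` and measures how Gabor-like the map is.

    Raises ``ValueError`` on a constant map.
    """
    rf = np.asarray(rf, dtype=float)
    if rf.ndim != 2:
        raise ValueError("rf must be a 2-D map")
    ss_tot = float(np.sum((rf - rf.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("constant RF map: Gabor fit is degenerate")

    rng = np.random.default_rng(seed)
    xx, yy = patch_grid(rf.shape, px_per_deg)
    extent_x = xx.max() - xx.min()
    extent_y = yy.max() - yy.min()
    px_deg = 1.0 / px_per_deg

    energy = (rf - rf.mean()) ** 2
    cx = float(np.sum(xx * energy) / np.sum(energy))
    cy = float(np.sum(yy * energy) / np.sum(energy))
    f0, theta0 = _spectral_init(rf, px_per_deg)
    amp0 = float(np.max(np.abs(rf - rf.mean())))
    sig0 = max(0.25 * extent_x, 2 * px_deg)

    target = rf.ravel()

    def residuals(p):
        x0, y0, th, f, phi, sx, sy, a, c = p
        return _gabor_eval(xx, yy, x0, y0, th, f, phi, sx, sy, a, c).ravel() - target

    lo = [xx.min(), yy.min(), -np.inf, 0.0, -np.inf, 0.2 * px_deg, 0.2 * px_deg, -np.inf, -np.inf]
    hi = [xx.max(), yy.max(), np.inf, 1.5 * px_per_deg / 2.0, np.inf, 2 * extent_x, 2 * extent_y, np.inf, np.inf]

    best = None
    n_done = 0
    # Deterministic starts: the spectral/centroid init with four carrier
    # phases, then seeded jitters of it.
    phase_starts = [0.0, np.pi / 2, np.pi, -np.pi / 2]
    for k in range(max(1, restarts)):
        phi0 = phase_starts[k % len(phase_starts)]
        p0 = np.array([cx, cy, np.deg2rad(theta0), f0, phi0, sig0, sig0, amp0, float(rf.mean())])
        if k >= len(phase_starts):
            p0[0] += rng.normal(0, 0.1 * extent_x)
            p0[1] += rng.normal(0, 0.1 * extent_y)
            p0[2] += rng.normal(0, 0.3)
            p0[3] *= rng.uniform(0.7, 1.4)
            p0[5] *= rng.uniform(0.6, 1.6)
            p0[6] *= rng.uniform(0.6, 1.6)
        p0 = np.clip(p0, lo, hi)
        try:
            sol = optimize.least_squares(residuals, p0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        n_done += 1
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        raise RuntimeError("Gabor fit failed on all restarts")

    x0, y0, th, f, phi, sx, sy, a, c = best.x
    params = GaborParams(
        x0=float(x0),
        y0=float(y0),
        theta_deg=float(np.rad2deg(th)),
        freq=float(f),
        phase_deg=float(np.rad2deg(phi)),
        sigma_x=float(sx),
        sigma_y=float(sy),
        amplitude=float(a),
        offset=float(c),
    )
    params = canonicalize(params)
    ss_res = float(2 * best.cost)
    return GaborFit(
        params=params,
        r2=1.0 - ss_res / ss_tot,
        ss_res=ss_res,
        success=bool(best.success),
        n_restarts=n_done,
    )


def canonicalize(p: GaborParams) -> GaborParams:
    """Map a Gabor parameter vector to a canonical equivalent form.

    The Gabor is invariant under (amplitude, phase) -> (-amplitude,
    phase+180) and under (theta, phase) -> (theta+180, -phase); orientation
    is reduced to [0, 180) with positive amplitude and phase in (-180, 180].
    """
    x0, y0, th, f, phi, sx, sy, a, c = (
        p.x0, p.y0, p.theta_deg, p.freq, p.phase_deg, p.sigma_x, p.sigma_y, p.amplitude, p.offset,
    )
    if a < 0:
        a, phi = -a, phi + 180.0
    th_mod = th % 360.0
    if th_mod >= 180.0:
        th_mod -= 180.0
        phi = -phi
    phi = ((phi + 180.0) % 360.0) - 180.0
    return GaborParams(x0, y0, th_mod, f, phi, sx, sy, a, c)


@dataclass
class FSV:
    """Frequency-normalised spread vector [n_x, n_y] = [sigma_x, sigma_y] * f."""

    n_x: float
    n_y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.n_x, self.n_y])


def fsv(fit: GaborFit | GaborParams) -> FSV:
    p = fit.params if isinstance(fit, GaborFit) else fit
    return FSV(n_x=p.sigma_x * p.freq, n_y=p.sigma_y * p.freq)


def fsv_square_fraction(fsvs, bound: float = 0.5) -> float:
    """Fraction of FSVs strictly inside the square n_x < bound and n_y < bound."""
    fsvs = list(fsvs)
    if len(fsvs) == 0:
        raise ValueError("empty FSV list")
    arr = np.array([[v.n_x, v.n_y] if isinstance(v, FSV) else tuple(v) for v in fsvs], dtype=float)
    return float(np.mean((arr[:, 0] < bound) & (arr[:, 1] < bound)))


def fit_rfset(rfs, px_per_deg: float, restarts: int = 4, seed: int = 0, r2_min: float = 0.5):
    """Fit every RF map in a stack and return a population summary.

    Returns (list of GaborFit, list of FSV restricted to fits with
    ``r2 >= r2_min``).  The threshold excludes maps the Gabor model does not
    describe, which would otherwise contribute meaningless shape vectors.
    """
    fits = []
    kept = []
    for i, rf in enumerate(rfs):
        try:
            ft = fit_gabor(np.asarray(rf), px_per_deg, restarts=restarts, seed=seed + i)
        except (ValueError, RuntimeError):
            fits.append(None)
            continue
        fits.append(ft)
        if ft.r2 >= r2_min:
            kept.append(fsv(ft))
    return fits, kept
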
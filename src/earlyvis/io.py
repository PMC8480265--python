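"""HDF5 / CSV persistence for datasets, models and analysis tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .frontend import PCATransform
from .ica import ICAModel
from .sc import SCModel
from .stdp import STDPNet, STDPRule
from .synthetic import PatchSet, ReferenceSample


def save_patchset(path: str | Path, ps: PatchSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=ps.patches, compression="gzip")
        f.create_dataset("coords", data=ps.source_coords)
        f.attrs["patch_deg"] = ps.patch_deg
        f.attrs["px_per_deg"] = ps.px_per_deg
        if ps.seed is not None:
            f.attrs["seed"] = ps.seed


def load_patchset(path: str | Path) -> PatchSet:
    with h5py.File(path, "r") as f:
        return PatchSet(
            patches=f["patches"][...],
            source_coords=f["coords"][...],
            patch_deg=float(f.attrs["patch_deg"]),
            px_per_deg=float(f.attrs["px_per_deg"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_sc_model(path: str | Path, m: SCModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=m.A)
        if m.gain is not None:
            f.create_dataset("gain", data=m.gain)
        f.attrs["lam"] = m.lam
        f.attrs["input_variance"] = m.input_variance
        if m.seed is not None:
            f.attrs["seed"] = m.seed


def load_sc_model(path: str | Path) -> SCModel:
    with h5py.File(path, "r") as f:
        return SCModel(
            A=f["A"][...],
            gain=f["gain"][...] if "gain" in f else None,
            lam=float(f.attrs["lam"]),
            input_variance=float(f.attrs["input_variance"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_ica_model(path: str | Path, m: ICAModel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=m.W)
        f.create_dataset("W_white", data=m.W_white)
        f.create_dataset("scale", data=m.scale)
        f.create_dataset("pca/mean", data=m.pca.mean)
        f.create_dataset("pca/components", data=m.pca.components)
        f.create_dataset("pca/explained_variance", data=m.pca.explained_variance)
        f.attrs["converged"] = m.converged
        f.attrs["n_iter"] = m.n_iter
        f.attrs["contrast"] = m.contrast


def load_ica_model(path: str | Path) -> ICAModel:
    with h5py.File(path, "r") as f:
        pca = PCATransform(
            mean=f["pca/mean"][...],
            components=f["pca/components"][...],
            explained_variance=f["pca/explained_variance"][...],
        )
        return ICAModel(
            W=f["W"][...], W_white=f["W_white"][...], scale=f["scale"][...],
            pca=pca, converged=bool(f.attrs["converged"]),
            n_iter=int(f.attrs["n_iter"]), contrast=str(f.attrs["contrast"]),
        )


def save_stdp_net(path: str | Path, net: STDPNet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=net.weights)
        if net.polarity is not None:
            f.create_dataset("polarity", data=net.polarity)
        f.attrs["theta"] = net.theta
        f.attrs["inhibition"] = net.inhibition
        r = net.rule
        f.attrs["rule"] = [r.alpha_plus, r.alpha_minus, r.mu_plus, r.mu_minus,
                           r.w_min, r.w_max]
        if net.seed is not None:
            f.attrs["seed"] = net.seed


def load_stdp_net(path: str | Path) -> STDPNet:
    with h5py.File(path, "r") as f:
        ap, am, mp, mm, wmin, wmax = f.attrs["rule"]
        return STDPNet(
            weights=f["weights"][...],
            polarity=f["polarity"][...] if "polarity" in f else None,
            theta=float(f.attrs["theta"]),
            inhibition=str(f.attrs["inhibition"]),
            rule=STDPRule(alpha_plus=ap, alpha_minus=am, mu_plus=mp, mu_minus=mm,
                          w_min=wmin, w_max=wmax),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_rfset(path: str | Path, maps: np.ndarray, px_per_deg: float,
               patch_deg: float, model_tag: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rfs", data=np.asarray(maps))
        f.attrs["px_per_deg"] = px_per_deg
        f.attrs["patch_deg"] = patch_deg
        f.attrs["model"] = model_tag


def load_rfset(path: str | Path):
    with h5py.File(path, "r") as f:
        return f["rfs"][...], dict(f.attrs)


def save_reference_csv(path: str | Path, ref: ReferenceSample) -> None:
    df = pd.DataFrame(ref.values, columns=ref.variables)
    df.to_csv(path, index=False)


def load_reference_csv(path: str | Path, provenance: str = "external-file") -> ReferenceSample:
    df = pd.read_csv(path)
    return ReferenceSample(variables=list(df.columns), values=df.to_numpy(float),
                           provenance=provenance)


def gabor_fit_table(fits, fsvs_all=None) -> pd.DataFrame:
    """Per-unit Gabor fit table (8 shape parameters, amplitude/offset, R2, FSV)."""
    rows = []
    for i, ft in enumerate(fits):
        if ft is None:
            rows.append({"unit": i})
            continue
        p = ft.params
        rows.append({
            "unit": i, "x0_deg": p.x0, "y0_deg": p.y0, "theta_deg": p.theta_deg,
            "freq_cpd": p.freq, "phase_deg": p.phase_deg,
            "sigma_x_deg": p.sigma_x, "sigma_y_deg": p.sigma_y,
            "amplitude": p.amplitude, "offset": p.offset, "r2": ft.r2,
            "n_x": p.sigma_x * p.freq, "n_y": p.sigma_y * p.freq,
        })
    return pd.DataFrame(rows)
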
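"""End-to-end orchestration of the train / probe / compare experiments.

The stages write their artifacts (HDF5 datasets and models, CSV tables)
into a run directory together with the resolved configuration and its
hash, so a run is reproducible from the directory alone.  All stages share
one master seed; every stochastic step derives its own stream from it.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import frontend, gabor, ica, io, probing, sc, stats, stdp, synthetic
from .config import config_hash, dump_config

log = logging.getLogger("earlyvis")

MODELS = ("stdp", "ica", "sc")


def _seed(cfg: dict, offset: int) -> int:
    return (int(cfg["seed"]) + offset) % (2**31 - 1)


def generate_dataset(cfg: dict, outdir: str | Path) -> dict:
    """Create (or load) images, sample the shared patch stream, and write
    both the raw and the whitened patch matrices.

    The whitened patches are extracted at the same coordinates as the raw
    ones so every model sees the same input sequence.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = cfg["data"]
    if d["n_patches"] < 1:
        raise ValueError("n_patches must be >= 1")
    if d["source"] == "synthetic":
        gen = (synthetic.gen_natural_surrogate_images
               if d.get("structure", "gabors") == "gabors"
               else synthetic.gen_pink_noise_images)
        images = gen(n=d["n_images"], field_deg=d["field_deg"],
                     px_per_deg=d["px_per_deg"], exponent=d["spectral_exponent"],
                     seed=_seed(cfg, 1))
    else:
        images = frontend.load_image_dir(d["image_dir"], px_per_deg=d["px_per_deg"])
    ps = synthetic.sample_patches(images, d["n_patches"], d["patch_deg"],
                                  seed=_seed(cfg, 2))
    white = frontend.whiten_imageset(images)
    k = ps.patch_px
    wstack = np.asarray(white.images)
    wpatches = np.empty_like(ps.patches)
    for j, (i, r, c) in enumerate(ps.source_coords):
        wpatches[j] = wstack[i, r:r + k, c:c + k].ravel()
    wps = synthetic.PatchSet(patches=wpatches, patch_deg=ps.patch_deg,
                             px_per_deg=ps.px_per_deg,
                             source_coords=ps.source_coords, seed=ps.seed)
    io.save_patchset(outdir / "patches.h5", ps)
    io.save_patchset(outdir / "patches_whitened.h5", wps)
    dump_config(cfg, outdir / "config.yaml")
    (outdir / "config.hash").write_text(config_hash(cfg))
    log.info("dataset: %d patches of %d px written to %s", ps.n_patches, k, outdir)
    return {"patches": ps, "whitened": wps}


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"{what} missing: {path}; run the earlier stage first")
    return path


def train_model(cfg: dict, model: str, outdir: str | Path) -> Path:
    """Train one encoding model on the shared patch stream."""
    outdir = Path(outdir)
    ps = io.load_patchset(_require(outdir / "patches.h5", "patch dataset"))
    k = ps.patch_px
    if model == "sc":
        wps = io.load_patchset(_require(outdir / "patches_whitened.h5",
                                        "whitened patches"))
        m = sc.sc_learn(wps, n_units=cfg["sc"]["n_units"], epochs=cfg["sc"]["epochs"],
                        batch=cfg["sc"]["batch"], infer_iters=cfg["sc"]["infer_iters"],
                        seed=_seed(cfg, 10))
        io.save_sc_model(outdir / "sc_model.h5", m)
        pd.DataFrame({"mean_sq_residual": m.training_log["mean_sq_residual"]}
                     ).to_csv(outdir / "sc_training_log.csv", index=False)
        log.info("sc: %d weights", m.n_weights)
        return outdir / "sc_model.h5"
    if model == "ica":
        c = cfg["ica"]
        m = ica.ica_fit_patches(ps, d=c["d"], contrast=c["contrast"], tol=c["tol"],
                                max_iter=c["max_iter"], seed=_seed(cfg, 11))
        io.save_ica_model(outdir / "ica_model.h5", m)
        log.info("ica: %d weights, converged=%s in %d iterations",
                 m.n_weights, m.converged, m.n_iter)
        return outdir / "ica_model.h5"
    if model == "stdp":
        c = cfg["stdp"]
        bank = frontend.build_lgn_bank(patch_px=k, px_per_deg=ps.px_per_deg,
                                       sigma_c_deg=c["sigma_c_deg"],
                                       surround_ratio=c["surround_ratio"],
                                       mode=c["mode"])
        net = stdp.init_net(n_neurons=c["n_neurons"], n_afferents=bank.n_afferents,
                            theta=c["theta"], seed=_seed(cfg, 12),
                            top_fraction=c["top_fraction"])
        tlog = stdp.stdp_train(net, ps, bank, top_fraction=c["top_fraction"])
        io.save_stdp_net(outdir / "stdp_net.h5", net)
        pd.DataFrame({"mean_abs_dw": tlog["mean_abs_dw_per_block"]}
                     ).to_csv(outdir / "stdp_training_log.csv", index=False)
        log.info("stdp: %d weights, %d patches skipped", net.n_weights,
                 tlog["n_skipped"])
        return outdir / "stdp_net.h5"
    raise ValueError(f"unknown model {model!r}")


def _load_bank_net(cfg: dict, outdir: Path):
    net = io.load_stdp_net(_require(outdir / "stdp_net.h5", "trained STDP net"))
    ps = io.load_patchset(outdir / "patches.h5")
    c = cfg["stdp"]
    bank = frontend.build_lgn_bank(patch_px=ps.patch_px, px_per_deg=ps.px_per_deg,
                                   sigma_c_deg=c["sigma_c_deg"],
                                   surround_ratio=c["surround_ratio"], mode=c["mode"])
    return net, bank, ps


def rf_maps_for(cfg: dict, model: str, outdir: Path) -> np.ndarray:
    ps = io.load_patchset(outdir / "patches.h5")
    k = ps.patch_px
    if model == "sc":
        m = io.load_sc_model(_require(outdir / "sc_model.h5", "trained SC model"))
        return sc.sc_rf_maps(m, k)
    if model == "ica":
        m = io.load_ica_model(_require(outdir / "ica_model.h5", "trained ICA model"))
        return ica.ica_rf_maps(m, k)
    net, bank, _ = _load_bank_net(cfg, outdir)
    return stdp.stdp_recover_rfs(net, bank)


def analyze_rf(cfg: dict, outdir: str | Path, models=MODELS,
               restarts: int = 4) -> dict:
    """Gabor fits, FSV tables and in-square fractions per model."""
    outdir = Path(outdir)
    ps = io.load_patchset(outdir / "patches.h5")
    out = {}
    for model in models:
        maps = rf_maps_for(cfg, model, outdir)
        fits, fsvs = gabor.fit_rfset(maps, ps.px_per_deg, restarts=restarts,
                                     seed=_seed(cfg, 20),
                                     r2_min=cfg["probe"]["r2_min"])
        table = io.gabor_fit_table(fits)
        table.to_csv(outdir / f"rf_{model}.csv", index=False)
        frac = gabor.fsv_square_fraction(fsvs) if fsvs else float("nan")
        out[model] = {"fits": fits, "fsvs": fsvs, "square_fraction": frac}
        log.info("rf %s: %d/%d usable fits, in-square fraction %.3f",
                 model, len(fsvs), len(maps), frac)
    return out


def _responders(cfg: dict, outdir: Path, models):
    """Population responders per model (STDP in spike mode)."""
    res = {}
    for model in models:
        if model == "stdp":
            net, bank, _ = _load_bank_net(cfg, outdir)
            res[model] = probing.stdp_responder(net, bank, mode="spike",
                                                top_fraction=cfg["stdp"]["top_fraction"])
        else:
            maps = rf_maps_for(cfg, model, outdir)
            res[model] = probing.linear_rectified_responder(maps)
    return res


def analyze_otc(cfg: dict, outdir: str | Path, models=MODELS,
                rf_result: dict | None = None, max_units: int | None = None,
                reps: int | None = None,
                phase_step_deg: float | None = None) -> dict:
    """Per-unit orientation tuning bandwidths at 0 dB SNR."""
    outdir = Path(outdir)
    ps = io.load_patchset(outdir / "patches.h5")
    pr = cfg["probe"]
    nyq = ps.px_per_deg / 2.0
    rf_result = rf_result or analyze_rf(cfg, outdir, models)
    out = {}
    for model in models:
        maps = rf_maps_for(cfg, model, outdir)
        fits = rf_result[model]["fits"]
        if model == "stdp":
            net, bank, _ = _load_bank_net(cfg, outdir)
        rows = []
        idx = [i for i, ft in enumerate(fits)
               if ft is not None and ft.r2 >= pr["r2_min"]]
        if max_units is not None:
            idx = idx[:max_units]
        for i in idx:
            freq = min(max(fits[i].freq, 0.1), nyq)
            if model == "stdp":
                full = probing.stdp_responder(net, bank, mode="potential",
                                              top_fraction=cfg["stdp"]["top_fraction"])
                unit = (lambda p, i=i, full=full: full(p)[i])
            else:
                rect = probing.linear_rectified_responder(maps[i:i + 1])
                unit = (lambda p, rect=rect: rect(p)[0])
            otc = probing.estimate_otc(unit, freq, snr_db=0.0,
                                       orient_step_deg=pr["otc_orient_step_deg"],
                                       phase_step_deg=phase_step_deg
                                       or pr["otc_phase_step_deg"],
                                       reps=reps or pr["reps"],
                                       patch_px=ps.patch_px,
                                       px_per_deg=ps.px_per_deg,
                                       seed=_seed(cfg, 30 + i))
            rows.append({"unit": i, "bandwidth_deg": otc.bandwidth_deg,
                         "ci_lo": otc.ci95[0] if otc.ci95 else np.nan,
                         "ci_hi": otc.ci95[1] if otc.ci95 else np.nan})
        df = pd.DataFrame(rows)
        df.to_csv(outdir / f"otc_{model}.csv", index=False)
        out[model] = df
        log.info("otc %s: %d units, median bandwidth %.1f deg", model, len(df),
                 float(df["bandwidth_deg"].median()) if len(df) else float("nan"))
    return out


def analyze_fi_decode(cfg: dict, outdir: str | Path, models=MODELS,
                      do_fi: bool = True, do_decode: bool = True,
                      decode_reps: int | None = None) -> dict:
    """FI and linear-decoding accuracy across the SNR grid, per model."""
    outdir = Path(outdir)
    ps = io.load_patchset(outdir / "patches.h5")
    pr = cfg["probe"]
    responders = _responders(cfg, outdir, models)
    rows_fi, rows_dec = [], []
    for model in models:
        for snr in pr["snr_db_grid"]:
            rm = probing.population_responses(
                responders[model], np.arange(0.0, 180.0, pr["orient_step_deg"]),
                pr["frequency"], pr["n_phases"], snr, pr["reps"],
                ps.patch_px, ps.px_per_deg, seed=_seed(cfg, 40))
            if do_fi:
                est = probing.estimate_fi(rm)
                rows_fi.append({"model": model, "snr_db": snr, "mean_fi": est.mean_J,
                                "ci_lo": est.ci95[0], "ci_hi": est.ci95[1]})
            if do_decode:
                dec = probing.linear_decode(rm, folds=5,
                                            reps=decode_reps or min(20, pr["reps"]),
                                            seed=_seed(cfg, 41))
                rows_dec.append({"model": model, "snr_db": snr,
                                 "accuracy": dec.accuracy, "ci_lo": dec.ci95[0],
                                 "ci_hi": dec.ci95[1], "chance": dec.chance})
    out = {}
    if do_fi:
        out["fi"] = pd.DataFrame(rows_fi)
        out["fi"].to_csv(outdir / "fi_vs_snr.csv", index=False)
    if do_decode:
        out["decode"] = pd.DataFrame(rows_dec)
        out["decode"].to_csv(outdir / "decode_vs_snr.csv", index=False)
    return out


def analyze_threshold_sweep(cfg: dict, outdir: str | Path,
                            snr_db_grid=None, reps=None) -> pd.DataFrame:
    outdir = Path(outdir)
    net, bank, ps = _load_bank_net(cfg, outdir)
    pr = cfg["probe"]
    sweep = probing.threshold_sweep_fi(
        net, bank, scales=pr["threshold_scales"],
        snr_db_grid=snr_db_grid or pr["snr_db_grid"],
        frequency=pr["frequency"], reps=reps or pr["reps"],
        orient_step_deg=pr["orient_step_deg"], n_phases=pr["n_phases"],
        seed=_seed(cfg, 50), top_fraction=cfg["stdp"]["top_fraction"])
    rows = [{"scale": s, "snr_db": snr, "mean_fi": sweep["mean_fi"][i, j]}
            for i, s in enumerate(sweep["scales"])
            for j, snr in enumerate(sweep["snr_db"])]
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "threshold_sweep_fi.csv", index=False)
    return df


def analyze_sparsity(cfg: dict, outdir: str | Path, models=MODELS) -> dict:
    """Spatial/temporal Gini profiles on naturalistic patches."""
    outdir = Path(outdir)
    ps = io.load_patchset(outdir / "patches.h5")
    n = min(cfg["probe"]["sparsity_patches"], ps.n_patches)
    rng = np.random.default_rng(_seed(cfg, 60))
    pick = rng.choice(ps.n_patches, size=n, replace=False)
    X = ps.patches[pick]
    out = {}
    rows = []
    for model in models:
        if model == "ica":
            m = io.load_ica_model(_require(outdir / "ica_model.h5", "ICA model"))
            act = ica.ica_activity(m, X).T                      # stimuli x units
        elif model == "sc":
            m = io.load_sc_model(_require(outdir / "sc_model.h5", "SC model"))
            wps = io.load_patchset(outdir / "patches_whitened.h5")
            act = sc.sc_infer_batch(m, wps.patches[pick], iters=100)
        else:
            net, bank, _ = _load_bank_net(cfg, outdir)
            act = np.stack([stdp.stdp_respond(net, x, bank, mode="potential",
                                              top_fraction=cfg["stdp"]["top_fraction"])
                            for x in X])
        prof = stats.sparsity_profile(act)
        out[model] = prof
        rows.append({"model": model,
                     "spatial_mean": float(np.nanmean(prof.spatial)),
                     "spatial_var": float(np.nanvar(prof.spatial)),
                     "temporal_mean": float(np.nanmean(prof.temporal)),
                     "temporal_var": float(np.nanvar(prof.temporal))})
        pd.DataFrame({"spatial": pd.Series(prof.spatial),
                      "temporal": pd.Series(prof.temporal)}
                     ).to_csv(outdir / f"sparsity_{model}.csv", index=False)
    pd.DataFrame(rows).to_csv(outdir / "sparsity_summary.csv", index=False)
    return out


def analyze_kl(cfg: dict, outdir: str | Path, models=MODELS,
               reference_fsv=None, reference_bw=None,
               rf_result: dict | None = None,
               otc_result: dict | None = None) -> pd.DataFrame:
    """KL divergence (bits) of the reference FSV/bandwidth distributions
    from each model's distributions; mirrors a joint + marginals layout."""
    outdir = Path(outdir)
    if reference_fsv is None:
        reference_fsv = synthetic.gen_reference_sample("fsv", 300, seed=_seed(cfg, 70))
    rf_result = rf_result or analyze_rf(cfg, outdir, models)
    ref_joint = stats.estimate_pdf(reference_fsv.values, ["n_x", "n_y"])
    ref_nx = stats.estimate_pdf(reference_fsv.values[:, 0], ["n_x"])
    ref_ny = stats.estimate_pdf(reference_fsv.values[:, 1], ["n_y"])
    rows = []
    for model in models:
        arr = np.array([[v.n_x, v.n_y] for v in rf_result[model]["fsvs"]])
        row = {"model": model}

        def _kl(ref_density, sample):
            # degenerate model samples (too few usable units, or collapsed
            # onto one value) carry no density estimate
            try:
                return stats.kl_divergence(ref_density, stats.estimate_pdf(sample))
            except ValueError:
                return np.nan

        if len(arr) >= 2:
            row.update(kl_joint_bits=_kl(ref_joint, arr),
                       kl_nx_bits=_kl(ref_nx, arr[:, 0]),
                       kl_ny_bits=_kl(ref_ny, arr[:, 1]))
        if otc_result is not None and model in otc_result:
            bw = otc_result[model]["bandwidth_deg"].dropna().to_numpy()
            if reference_bw is None:
                reference_bw = synthetic.gen_reference_sample("bandwidth", 300,
                                                              seed=_seed(cfg, 71))
            if len(bw) >= 2:
                row["kl_bandwidth_bits"] = _kl(
                    stats.estimate_pdf(reference_bw.values[:, 0]), bw)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "kl_table.csv", index=False)
    return df
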
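"""End-to-end orchestration: simulate -> normalize -> fourier -> predict ->
GRF-SPM -> allometry, with schema validation and a run manifest.

Every run writes a ``run_manifest.json`` echoing the full configuration,
the seed, the package version, and a SHA-256 content hash of every output
file, so deterministic stages can be verified bit-for-bit on re-run.
"""
from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import substream
from .cohort import generate_cohort
from .config import CohortConfig, load_config
from .dynamics import spm_two_sample, summarize_grf
from .errors import IntegrityError, PigaitError
from .kinematics import JOINTS
from .musculo import allometric_fit, isometry_test, limb_capacity_table
from .normalization import normalize_stride_table
from .predictive import build_feature_table, predict, train, validate

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "validate_tables", "sha256_file"]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------- validation

def _check(frame: pd.DataFrame, name: str, condition, message: str, problems: list):
    bad = ~condition
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        problems.append(f"{name}: row {idx}: {message}")


def validate_tables(paths: dict) -> dict:
    """Schema/invariant report for the standard CSV tables.

    ``paths`` maps table name (piglets, strides, joint_traces, grf_traces,
    muscles, energetics) to file path.  Returns per-table
    ``{"ok": bool, "problems": [...], "n_rows": int}``; missing optional
    tables pass with a note.
    """
    report = {}
    for name, path in paths.items():
        path = Path(path)
        if not path.exists():
            report[name] = {"ok": False, "problems": [f"file not found: {path}"], "n_rows": 0}
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # unreadable file
            report[name] = {"ok": False, "problems": [f"unreadable: {exc}"], "n_rows": 0}
            continue
        problems: list = []
        if len(df) == 0:
            report[name] = {"ok": True, "problems": ["empty table"], "n_rows": 0}
            continue
        if name == "piglets":
            _check(df, name, df["birth_mass_kg"] > 0, "birth_mass_kg <= 0", problems)
            for col in df.columns:
                if col.startswith("seg_"):
                    _check(df, name, df[col] > 0, f"{col} <= 0", problems)
        elif name == "strides":
            _check(df, name, df["stride_time_s"] > 0, "stride_time_s <= 0", problems)
            _check(df, name, df["stance_time_s"] <= df["stride_time_s"],
                   "stance_time_s > stride_time_s", problems)
            _check(df, name, (df["duty_factor"] > 0) & (df["duty_factor"] <= 1),
                   "duty_factor outside (0, 1]", problems)
            _check(df, name, df["hip_height_midstance_m"] > 0,
                   "hip_height_midstance_m <= 0", problems)
            consistency = np.abs(
                df["speed_ms"] - df["stride_length_m"] * df["stride_frequency_hz"]
            )
            _check(df, name, consistency < 1e-9, "V != L * F", problems)
            for col in ("phase_diagonal", "phase_ipsilateral", "phase_girdle"):
                _check(df, name, (df[col] >= 0) & (df[col] < 1),
                       f"{col} outside [0, 1)", problems)
        elif name == "joint_traces":
            _check(df, name, (df["angle_rad"] > 0) & (df["angle_rad"] < np.pi),
                   "angle_rad outside (0, pi)", problems)
            _check(df, name, df["joint"].isin(JOINTS), "unknown joint", problems)
        elif name == "grf_traces":
            vert = df["component"] == "vertical"
            _check(df[vert], name, df.loc[vert, "force_bw"] >= 0,
                   "negative vertical force", problems)
            _check(df, name, (df["stance_fraction"] >= 0) & (df["stance_fraction"] <= 1),
                   "stance_fraction outside [0, 1]", problems)
        elif name == "muscles":
            _check(df, name, df["mass_kg"] > 0, "mass_kg <= 0", problems)
            _check(df, name, df["fibre_length_m"] > 0, "fibre_length_m <= 0", problems)
        report[name] = {"ok": not problems, "problems": problems, "n_rows": len(df)}
    return report


# ------------------------------------------------------------------ pipeline

def run_pipeline(
    config,
    outdir,
    seed: int = 0,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    interval_level: float = 0.9,
) -> dict:
    """Execute the full analysis on a simulated cohort; returns the manifest.

    ``config`` is a :class:`CohortConfig` or a path to a YAML config.
    Stages run in dependency order; any failure raises with the stage name.
    """
    if not isinstance(config, CohortConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "seed": int(seed),
        "config": config.to_dict(),
        "started_utc": datetime.now(timezone.utc).isoformat(),
        "stages": {},
        "hashes": {},
    }
    stage = "simulate"
    try:
        data = generate_cohort(config, seed)
        paths = data.write_csvs(outdir)
        manifest["stages"][stage] = {"n_piglets": len(data.piglets),
                                     "n_strides": len(data.strides)}

        stage = "validate"
        report = validate_tables(paths)
        bad = {k: v for k, v in report.items() if not v["ok"]}
        if bad:
            raise IntegrityError(f"table validation failed: {bad}")
        manifest["stages"][stage] = {k: v["n_rows"] for k, v in report.items()}

        stage = "normalize"
        norm = normalize_stride_table(data.strides, g=config.gravity)
        norm.to_csv(outdir / "strides_dimensionless.csv", index=False, float_format="%.12g")
        manifest["stages"][stage] = {"n_rows": len(norm)}

        stage = "fourier"
        aga = norm[norm["category"] == "AGA"]
        rest = norm[norm["category"] != "AGA"]
        feats_aga, pca = build_feature_table(aga, data.joint_traces, data.piglets)
        frames = [feats_aga]
        if len(rest):
            feats_rest, _ = build_feature_table(rest, data.joint_traces, data.piglets, pca=pca)
            frames.append(feats_rest)
        features = pd.concat(frames, ignore_index=True)
        features.to_csv(outdir / "features.csv", index=False, float_format="%.12g")
        np.savetxt(outdir / "pca_loadings.csv", pca["loadings"], delimiter=",")
        manifest["stages"][stage] = {
            "n_strides": len(features),
            "explained_variance_12pc": float(pca["explained_variance_ratio"].sum()),
        }

        stage = "train-predict"
        rng = substream(seed, "holdout")
        n_holdout = min(35, max(1, len(feats_aga) // 5))
        holdout_idx = rng.choice(len(feats_aga), size=n_holdout, replace=False)
        mask = np.zeros(len(feats_aga), dtype=bool)
        mask[holdout_idx] = True
        train_f, valid_f = feats_aga[~mask], feats_aga[mask]
        results = {}
        pred_frames = []
        for target in ("mass", "size", "age"):
            model = train(train_f, train_f[f"actual_{target}"], target=target, seed=seed)
            results[target] = validate(
                model, valid_f, valid_f[f"actual_{target}"], level=interval_level
            )
            if len(rest):
                p = predict(model, feats_rest, level=interval_level)
                p["actual"] = feats_rest[f"actual_{target}"].to_numpy()
                p["difference"] = p["posterior_mean"] - p["actual"]
                pred_frames.append(p)
        if pred_frames:
            pd.concat(pred_frames, ignore_index=True).to_csv(
                outdir / "predictions.csv", index=False, float_format="%.12g"
            )
        manifest["stages"][stage] = results

        stage = "grf-spm"
        spm_out = {}
        for limb in ("fore", "hind"):
            for component in ("vertical", "fore_aft"):
                sub = data.grf_traces[
                    (data.grf_traces["limb"] == limb)
                    & (data.grf_traces["component"] == component)
                ]
                wide = sub.pivot(index="stride_id", columns="stance_fraction",
                                 values="force_bw")
                cats = data.strides.set_index("stride_id")["category"]
                a = wide.loc[cats[wide.index] == "AGA"].to_numpy()
                b = wide.loc[cats[wide.index] == "SGA"].to_numpy()
                if len(a) < 3 or len(b) < 3:
                    continue
                res = spm_two_sample(
                    a, b, alpha=alpha, n_permutations=n_permutations,
                    rng=substream(seed, f"spm-{limb}-{component}"),
                )
                spm_out[f"{limb}_{component}"] = {
                    "critical_threshold": res.critical_threshold,
                    "clusters": [
                        {"start": c.start, "end": c.end, "p": c.p_value}
                        for c in res.clusters
                    ],
                    "mean_curve": summarize_grf(np.vstack([a, b]))["mean"].tolist(),
                }
        with open(outdir / "spm_results.json", "w") as fh:
            json.dump(spm_out, fh, indent=1)
        manifest["stages"][stage] = {
            k: len(v["clusters"]) for k, v in spm_out.items()
        }

        stage = "allometry"
        allo = {}
        for part in ("front", "hind", "head"):
            fit = allometric_fit(
                data.piglets["birth_mass_kg"], data.piglets[f"{part}_mass_kg"]
            )
            allo[part] = {
                "a": fit.a, "b": fit.b, "b_ci": list(fit.b_ci),
                "r_squared": fit.r_squared, "n": fit.n,
                "isometry": isometry_test(fit),
            }
        with open(outdir / "allometry.json", "w") as fh:
            json.dump(allo, fh, indent=1)
        capacity = limb_capacity_table(data.muscles, data.piglets, g=config.gravity)
        capacity.to_csv(outdir / "limb_capacity.csv", index=False, float_format="%.12g")
        manifest["stages"][stage] = {p: allo[p]["b"] for p in allo}
    except PigaitError as exc:
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc

    for path in sorted(outdir.iterdir()):
        if path.name != "run_manifest.json" and path.is_file():
            manifest["hashes"][path.name] = sha256_file(path)
    manifest["finished_utc"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
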
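"""Dataset and configuration file handling.

Datasets use a NONMEM-dialect CSV: one row per event, columns

    ID, TIME, EVID (1=dose, 0=observation), AMT (mg), RATE (mg/h),
    DV (mg/L), MDV, plus uppercase covariate columns
    (AGE, SEX, WT, BMI, SCR, CCR, ALB, BUN, ALT, AST, ALP, GGT, TBIL,
    WBC, RBC, PLT, ...).

SEX is coded 1 = male, 0 = female.  Dose rows carry AMT and RATE and
MDV = 1; observation rows carry DV and MDV = 0.  TIME must be
non-decreasing within each subject.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tigepk.covariates import CovariateEffect, VarianceModel

__all__ = [
    "REQUIRED_COLUMNS",
    "read_dataset",
    "write_dataset",
    "validate_dataset",
    "load_config",
    "save_config",
    "write_manifest",
    "model_spec_to_dict",
    "model_spec_from_dict",
]

REQUIRED_COLUMNS = ["ID", "TIME", "EVID", "AMT", "RATE", "DV", "MDV"]


class DatasetError(ValueError):
    """Malformed PK dataset."""


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a NONMEM-dialect event table; returns the frame unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"dataset missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise DatasetError("dataset is empty")
    if not df["EVID"].isin([0, 1]).all():
        bad = df.loc[~df["EVID"].isin([0, 1])].index[0]
        raise DatasetError(f"EVID must be 0 or 1 (row {bad})")
    doses = df[df["EVID"] == 1]
    if (doses["AMT"] <= 0).any():
        bad = doses.loc[doses["AMT"] <= 0].index[0]
        raise DatasetError(f"non-positive dose AMT at row {bad}")
    if (doses["RATE"] <= 0).any():
        bad = doses.loc[doses["RATE"] <= 0].index[0]
        raise DatasetError(f"non-positive infusion RATE at row {bad}")
    for sid, g in df.groupby("ID", sort=False):
        t = g["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise DatasetError(f"TIME not non-decreasing within subject {sid}")
        if (g["EVID"] == 0).sum() == 0:
            raise DatasetError(f"subject {sid} has no observations")
    return df


def read_dataset(path: str | Path) -> pd.DataFrame:
    """Read and validate a NONMEM-dialect CSV dataset."""
    df = pd.read_csv(path)
    return validate_dataset(df)


def write_dataset(df: pd.DataFrame, path: str | Path) -> None:
    """Write a dataset CSV (validates first; floats round-trip losslessly)."""
    validate_dataset(df)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------- config --


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> dict:
    """Emit the run manifest JSON accompanying every artifact-producing run."""
    import datetime

    from tigepk import __version__

    manifest = {
        "command": command,
        "config": config,
        "master_seed": seed,
        "input_checksums": {str(p): sha256_file(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
        "tigepk_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# ------------------------------------------------------- model spec files --


def model_spec_to_dict(spec) -> dict:
    """Serialize a ModelSpec to a plain dict (YAML-safe; lossless round-trip)."""
    return {
        "n_compartments": spec.n_compartments,
        "covariate_effects": [
            {
                "parameter": e.parameter,
                "covariate": e.covariate,
                "form": e.form,
                "theta_cov": e.theta_cov,
                "cov_median": e.cov_median,
                "log10": e.log10,
            }
            for e in spec.covariate_effects
        ],
        "variance": {
            "omega": dict(spec.variance.omega),
            "sigma": spec.variance.sigma,
            "sigma_add": spec.variance.sigma_add,
            "residual_form": spec.variance.residual_form,
        },
        "fixed_initials": dict(spec.fixed_initials),
    }


def model_spec_from_dict(d: dict):
    from tigepk.estimation import ModelSpec

    effects = [CovariateEffect(**e) for e in d.get("covariate_effects", [])]
    v = d.get("variance", {})
    variance = VarianceModel(
        omega=dict(v.get("omega", {})),
        sigma=float(v.get("sigma", 2.02)),
        sigma_add=float(v.get("sigma_add", 0.0)),
        residual_form=v.get("residual_form", "proportional"),
    )
    return ModelSpec(
        n_compartments=int(d.get("n_compartments", 2)),
        covariate_effects=effects,
        variance=variance,
        fixed_initials=dict(d.get("fixed_initials", {})),
    )
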
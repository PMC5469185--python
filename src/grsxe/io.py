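"""Delimited-text I/O for cohorts, weights and run manifests.

A cohort is stored as one delimited table (one row per subject,
columns = SNP dosages in 0/1/2 coding, then the exposure column ``E``
and the binary outcome ``Y``) plus a JSON sidecar carrying the SNP
roles, the correlated-copy source map, the generative truth and the
seed.  A PLINK .raw-compatible export (additive dosages) is available
for interoperability.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Population
from .designs import EffectDesign, EnvironmentSpec, ScenarioConfig
from .scoring import WeightVector

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_plink_raw",
    "write_weights",
    "read_weights",
    "RunManifest",
    "write_manifest",
]

_RESERVED = ("E", "Y")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _design_to_dict(d: EffectDesign) -> dict:
    return {
        "snp_names": list(d.snp_names),
        "maf": list(map(float, d.maf)),
        "beta_g": list(map(float, d.beta_g)),
        "beta_gxe": list(map(float, d.beta_gxe)),
        "beta_e": d.beta_e,
        "target_prevalence": d.target_prevalence,
        "design_label": d.design_label,
    }


def _design_from_dict(d: dict) -> EffectDesign:
    return EffectDesign(
        snp_names=tuple(d["snp_names"]),
        maf=np.asarray(d["maf"]),
        beta_g=np.asarray(d["beta_g"]),
        beta_gxe=np.asarray(d["beta_gxe"]),
        beta_e=float(d["beta_e"]),
        target_prevalence=float(d["target_prevalence"]),
        design_label=str(d["design_label"]),
    )


def write_cohort(pop: Population, path, sep: str = "\t") -> Path:
    """Write the cohort table and its JSON sidecar; returns the table path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(pop.genotypes, columns=pop.snp_names)
    df["E"] = pop.exposure
    df["Y"] = pop.outcome
    df.to_csv(path, sep=sep, index=False)
    meta = {
        "roles": pop.roles,
        "source_map": {k: list(v) for k, v in pop.source_map.items()},
        "truth": _design_to_dict(pop.truth) if pop.truth is not None else None,
        "seed": pop.config.seed if pop.config is not None else None,
        "intercept": None if np.isnan(pop.intercept) else pop.intercept,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_cohort(path, sep: str = "\t") -> Population:
    """Read a cohort table, validating domains; attaches sidecar if present.

    Malformed genotype values are reported with their (1-based) file
    line number; a missing required column raises a schema error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in _RESERVED if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s) {missing}; "
            f"expected SNP columns plus {list(_RESERVED)}"
        )
    snp_cols = [c for c in df.columns if c not in _RESERVED]
    if not snp_cols:
        raise ValueError(f"{path.name}: no SNP columns found")
    G = df[snp_cols].to_numpy()
    bad = ~np.isin(G, (0, 1, 2)) | ~np.isfinite(G.astype(float))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        # +2: one for the header row, one for 1-based numbering
        raise ValueError(
            f"{path.name} line {i + 2}: invalid genotype value "
            f"{df.iloc[i][snp_cols[j]]!r} in column {snp_cols[j]} "
            "(expected 0/1/2)"
        )
    E = df["E"].to_numpy(dtype=float)
    if not np.all(np.isfinite(E)):
        i = int(np.flatnonzero(~np.isfinite(E))[0])
        raise ValueError(f"{path.name} line {i + 2}: non-numeric exposure")
    Y = df["Y"].to_numpy()
    if not np.isin(Y, (0, 1)).all():
        i = int(np.flatnonzero(~np.isin(Y, (0, 1)))[0])
        raise ValueError(f"{path.name} line {i + 2}: outcome must be 0/1")

    roles = ["unknown"] * len(snp_cols)
    source_map: dict = {}
    truth = None
    intercept = np.nan
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        roles = meta.get("roles", roles)
        source_map = {k: tuple(v) for k, v in meta.get("source_map", {}).items()}
        if meta.get("truth"):
            truth = _design_from_dict(meta["truth"])
        if meta.get("intercept") is not None:
            intercept = float(meta["intercept"])
    return Population(
        genotypes=G.astype(np.int8),
        exposure=E,
        outcome=Y.astype(np.int8),
        snp_names=snp_cols,
        roles=roles,
        source_map=source_map,
        truth=truth,
        config=None,
        intercept=intercept,
    )


def write_plink_raw(pop: Population, path) -> Path:
    """Additive-dosage export in the PLINK .raw dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = pop.n_individuals
    df = pd.DataFrame(
        {
            "FID": [f"F{i+1}" for i in range(n)],
            "IID": [f"I{i+1}" for i in range(n)],
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            # PLINK convention: 1 = control, 2 = case
            "PHENOTYPE": pop.outcome.astype(int) + 1,
        }
    )
    for j, name in enumerate(pop.snp_names):
        df[name] = pop.genotypes[:, j]
    df.to_csv(path, sep=" ", index=False)
    return path


def write_weights(wv: WeightVector, path) -> Path:
    """TSV of (snp_id, weight) plus a JSON sidecar with the fit metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = wv.snp_names or [f"snp{j}" for j in range(len(wv.weights))]
    pd.DataFrame({"snp": names, "weight": wv.weights}).to_csv(path, sep="\t", index=False)
    meta = {
        "alpha": wv.alpha,
        "lambda": wv.lambda_selected,
        "intercept": wv.intercept,
        "n_nonzero": wv.n_nonzero,
        "converged": wv.converged,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_weights(path) -> WeightVector:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    side = _sidecar_path(path)
    meta = json.loads(side.read_text()) if side.exists() else {}
    return WeightVector(
        weights=df["weight"].to_numpy(dtype=float),
        intercept=float(meta.get("intercept", 0.0)),
        alpha=float(meta.get("alpha", np.nan)),
        lambda_selected=float(meta.get("lambda", np.nan)),
        converged=bool(meta.get("converged", True)),
        snp_names=df["snp"].tolist(),
    )


@dataclasses.dataclass
class RunManifest:
    """Everything needed to replay a CLI run."""

    command: str
    config: dict
    seed: int
    package_version: str
    timestamp: str

    @classmethod
    def create(cls, command: str, config: dict, seed: int) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config=config,
            seed=seed,
            package_version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )


def write_manifest(manifest: RunManifest, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "run_manifest.json"
    out.write_text(json.dumps(dataclasses.asdict(manifest), indent=1))
    return out


def scenario_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["environment"] = {"name": config.environment.name, "params": list(config.environment.params)}
    return d


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    env = d.pop("environment", None)
    kwargs = {}
    if env:
        kwargs["environment"] = EnvironmentSpec(name=env["name"], params=tuple(env["params"]))
    rc = d.pop("randomization_counts", None)
    if rc is not None:
        kwargs["randomization_counts"] = tuple(rc)
    return ScenarioConfig(**{**d, **kwargs})
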
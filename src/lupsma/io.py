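"""Dataset reading/writing and layered configuration handling.

Datasets use the NONMEM-style event-record dialect: times in hours since the
first administration (0-based), dosing rows with EVID = 1 and AMT in MBq,
observation rows with EVID = 0, compartment codes 1 central (MBq/L),
2 salivary glands, 3 kidneys, 4 tumor (MBq) and 6 PSA (µg/L); missing DV is
written as ".".  Configuration files (YAML or JSON) are merged over the
shipped defaults; unknown keys raise rather than being silently ignored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimation import REQUIRED_COLUMNS, ObservationSet
from .params import PDParameters, PKParameters, VarianceParameters
from .population import cv_to_omega
from .simulation import CovariateSpec
from .synthetic import SamplingSchedule


def default_config() -> dict:
    """The shipped parameterization as a plain dict."""
    with resources.files("lupsma.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


@dataclass
class RunConfig:
    """Fully resolved run configuration.

    ``raw`` is the merged dict; typed parameter objects are derived from it.
    ``provenance`` records, per top-level section, whether any user override
    touched it.
    """

    raw: dict
    provenance: dict[str, str]

    @staticmethod
    def _val(node):
        return node["value"] if isinstance(node, dict) and "value" in node else node

    def pk_parameters(self) -> PKParameters:
        s = self.raw["pk"]["structural"]
        c = self.raw["pk"]["covariates"]
        v = self._val
        fr = c["cycle_fractions"]
        sal = None
        if self.raw["flags"].get("salivary_cycle_effect"):
            sal = (0.846, 0.981)
        return PKParameters(
            k10=v(s["k10"]), k12=v(s["k12"]), k21=v(s["k21"]), k13=v(s["k13"]),
            k31=v(s["k31"]), k14=v(s["k14"]), k41=v(s["k41"]), k15=v(s["k15"]),
            k51=v(s["k51"]), B_MAX_sal=v(s["B_MAX_sal"]), V1=v(s["V1"]),
            theta_TV_k12=v(c["theta_TV_k12"]), theta_TV_k14=v(c["theta_TV_k14"]),
            cycle_fractions=(fr["cycle2"], fr["cycle3"], fr["cycle4_7"]),
            WT_median=v(c["WT_median"]), TV_median=v(c["TV_median"]),
            allometric_exponent_k=c["allometric_exponent_k"],
            allometric_exponent_V=c["allometric_exponent_V"],
            salivary_cycle_fractions=sal,
        )

    def pd_parameters(self) -> PDParameters:
        s = self.raw["pd"]["structural"]
        v = self._val
        return PDParameters(
            PSA0=v(s["PSA0"]), theta_TV_PSA0=v(s["theta_TV_PSA0"]), kG=v(s["kG"]),
            kD_direct=v(s["kD_direct"]), ke0=v(s["ke0"]), kD_delay=v(s["kD_delay"]),
            boxcox_shape=v(s["boxcox_shape"]),
            baseline_covariate_form=self.raw["flags"]["baseline_psa_covariate"],
        )

    def variance_parameters(self) -> VarianceParameters:
        conv = self.raw["flags"]["cv_to_omega"]
        pk_iiv = self.raw["pk"]["iiv_cv_percent"]
        pd_iiv = self.raw["pd"]["iiv_cv_percent"]
        ruv = self.raw["pk"]["residual_error"]
        return VarianceParameters(
            omega_k10=cv_to_omega(pk_iiv["k10"], conv),
            omega_k13=cv_to_omega(pk_iiv["k13"], conv),
            omega_k14=cv_to_omega(pk_iiv["k14"], conv),
            omega_k15=cv_to_omega(pk_iiv["k15"], conv),
            omega_Bmax_sal=cv_to_omega(pk_iiv["B_MAX_sal"], conv),
            omega_iov_k14=cv_to_omega(self.raw["pk"]["iov_cv_percent"]["k14"], conv),
            omega_PSA0=cv_to_omega(pd_iiv["PSA0"], conv),
            omega_kG=cv_to_omega(pd_iiv["kG"], conv),
            omega_kDdirect=cv_to_omega(pd_iiv["kD_direct"], conv),
            omega_kDdelay=cv_to_omega(pd_iiv["kD_delay"], conv),
            sigma_prop_central=ruv["central"]["prop_cv_percent"] / 100.0,
            sigma_add_central=ruv["central"]["add_sd"],
            sigma_prop_salivary=ruv["salivary"]["prop_cv_percent"] / 100.0,
            sigma_prop_kidneys=ruv["kidneys"]["prop_cv_percent"] / 100.0,
            sigma_prop_tumor=ruv["tumor"]["prop_cv_percent"] / 100.0,
            sigma_prop_psa=self.raw["pd"]["residual_error"]["psa"]["prop_cv_percent"] / 100.0,
        )

    def covariate_specs(self) -> dict[str, CovariateSpec]:
        pop = self.raw["population"]
        return {
            name: CovariateSpec(median=pop[name]["median"], low=pop[name]["low"],
                                high=pop[name]["high"])
            for name in ("WT", "TV")
        }

    def sampling_schedule(self) -> SamplingSchedule:
        sch = self.raw["schedule"]
        return SamplingSchedule(
            scan_offset_means=tuple(sch["scan_offsets_h"]["means"]),
            scan_offset_sds=tuple(sch["scan_offsets_h"]["sds"]),
            psa_interval_weeks=sch["psa_interval_weeks"],
            baseline_psa_window_weeks=sch["baseline_psa_window_weeks"],
        )

    @property
    def solver(self) -> dict:
        return self.raw["solver"]

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON config merged over the shipped defaults."""
    base = default_config()
    provenance = {key: "default" for key in base}
    if path is not None:
        text = Path(path).read_text()
        user = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
        merged = _merge(base, user)
        for key in user:
            provenance[key] = "user"
        return RunConfig(raw=merged, provenance=provenance)
    return RunConfig(raw=base, provenance=provenance)


def write_dataset(obs: ObservationSet, path: str | Path) -> None:
    """Write an event dataset as CSV with missing DV coded as '.'."""
    df = obs.data.copy()
    df["DV"] = df["DV"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False)


def read_dataset(path: str | Path) -> ObservationSet:
    """Read and validate an event CSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, na_values=["."], keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset {path} missing columns: {missing}")
    for col in ("TIME", "AMT", "DV", "WT", "TV"):
        df[col] = df[col].astype(float)
    for col in ("ID", "EVID", "CMT", "MDV", "CYCLE"):
        df[col] = df[col].astype(int)
    if "OCC" in df.columns:
        df["OCC"] = df["OCC"].astype(int)
    return ObservationSet(df)


def write_manifest(path: str | Path, config: RunConfig, seed: int,
                   extra: dict | None = None) -> None:
    """Reproducibility manifest: config hash, seed, package version."""
    from . import __version__

    manifest = {
        "package": "lupsma",
        "version": __version__,
        "seed": seed,
        "config_hash": config.config_hash(),
        "provenance": config.provenance,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
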
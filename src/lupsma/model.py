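"""Model/Results interface over the PKPD machinery.

`PKPDModel` is built from a longitudinal event dataset (or constructed
parameter-only for pure simulation); `fit()` runs either naive-pooled
weighted least squares over selected structural parameters or per-subject
MAP (empirical-Bayes) estimation of random effects, and returns a
`PKPDResults` carrying estimates, uncertainties, diagnostics and a
`summary()` table.  Simulation of virtual populations and exposure–response
analysis hang off both objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import individualize
from .estimation import (MapResult, ObservationSet, map_estimate,
                         naive_pooled_fit, predict_observations)
from .exposure import (auc_threshold, fit_exposure_response, psa_percent_changes,
                       tumor_auc)
from .params import PDParameters, PKParameters, VarianceParameters
from .simulation import (Regimen, build_regimen, generate_virtual_population,
                         response_rates, simulate_population, vpc_summary)


class PKPDModel:
    """Population PKPD model for the radioligand, bound to a dataset.

    Parameters
    ----------
    dataset : ObservationSet or None
        Event data the model will be fitted to; may be None for a
        simulation-only model.
    params, pd_params, variances
        Population parameter objects; defaults are the published estimates.
    """

    def __init__(
        self,
        dataset: ObservationSet | None = None,
        params: PKParameters | None = None,
        pd_params: PDParameters | None = None,
        variances: VarianceParameters | None = None,
    ) -> None:
        self.dataset = dataset
        self.params = params if params is not None else PKParameters()
        self.pd_params = pd_params if pd_params is not None else PDParameters()
        self.variances = variances if variances is not None else VarianceParameters()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PKPDModel":
        return cls(dataset=ObservationSet(data), **kwargs)

    @classmethod
    def from_config(cls, config, dataset: ObservationSet | None = None) -> "PKPDModel":
        return cls(
            dataset=dataset,
            params=config.pk_parameters(),
            pd_params=config.pd_parameters(),
            variances=config.variance_parameters(),
        )

    # -- estimation ---------------------------------------------------------

    def fit(self, method: str = "pooled", free: list[str] | None = None,
            **kwargs) -> "PKPDResults":
        if self.dataset is None:
            raise ValueError("model has no dataset to fit")
        if method == "pooled":
            free = free or ["k10", "k14"]
            res = naive_pooled_fit(self.dataset, free, params=self.params,
                                   pd_params=self.pd_params,
                                   variances=self.variances, **kwargs)
            return PKPDResults(model=self, method="pooled", pooled=res)
        if method == "map":
            maps = {}
            for sid in self.dataset.subject_ids:
                obs = self.dataset.observations(sid)
                if not len(obs):
                    continue
                maps[sid] = map_estimate(
                    obs, self.dataset.regimen_for(sid),
                    self.dataset.covariates_for(sid),
                    self.params, self.pd_params, self.variances, **kwargs,
                )
            return PKPDResults(model=self, method="map", map_results=maps)
        raise ValueError(f"unknown method {method!r}; use 'pooled' or 'map'")

    # -- simulation ---------------------------------------------------------

    def simulate(self, regimen: str | Regimen = "4x6", n: int = 2000,
                 seed: int = 0, **kwargs):
        """Virtual-population trial simulation; returns (endpoints, trajectories)."""
        reg = build_regimen(regimen) if isinstance(regimen, str) else regimen
        pop = generate_virtual_population(n, seed, variances=self.variances,
                                          n_occasions=reg.n_cycles)
        return simulate_population(pop, reg, self.params, self.pd_params, **kwargs)

    def typical_individual(self, covariates=None, max_cycles: int = 4):
        from .params import CovariateSet

        cov = covariates if covariates is not None else CovariateSet()
        return individualize(self.params, self.pd_params, cov, max_cycles=max_cycles)


@dataclass
class PKPDResults:
    """Estimation results wrapper with a text summary."""

    model: PKPDModel
    method: str
    pooled: object | None = None
    map_results: dict[int, MapResult] = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        if self.method == "pooled":
            return pd.Series(self.pooled.estimates)
        rows = {sid: res.eta for sid, res in self.map_results.items()}
        return pd.DataFrame(rows).T.stack()

    @property
    def bse(self) -> pd.Series:
        if self.method != "pooled":
            raise AttributeError("standard errors only available for pooled fits")
        return pd.Series(self.pooled.se)

    @property
    def eta(self) -> pd.DataFrame:
        """Per-subject MAP random-effect estimates."""
        if self.method != "map":
            raise AttributeError("eta estimates only available for MAP fits")
        return pd.DataFrame({sid: r.eta for sid, r in self.map_results.items()}).T

    def predict(self, subject_id=None) -> np.ndarray:
        """Predictions at the dataset's observation rows."""
        ds = self.model.dataset
        sids = [subject_id] if subject_id is not None else ds.subject_ids
        out = []
        for sid in sids:
            obs = ds.observations(sid)
            if not len(obs):
                continue
            if self.method == "map":
                ip = self.map_results[sid].individual_params
            else:
                from .estimation import _apply_free

                pk, pdp = _apply_free(self.model.params, self.model.pd_params,
                                      self.pooled.estimates)
                ip = individualize(pk, pdp, ds.covariates_for(sid),
                                   max_cycles=max(ds.regimen_for(sid).n_cycles, 1))
            out.append(predict_observations(obs, ds.regimen_for(sid), ip))
        return np.concatenate(out) if out else np.array([])

    def exposure_response(self, endpoint: str = "nadir",
                          window_weeks: float = 12.0) -> dict:
        """MAP-based tumor AUC vs percent PSA change, with the −50% threshold."""
        if self.method != "map":
            raise ValueError("exposure-response analysis requires a MAP fit")
        from .exposure import ExposureRecord
        from .simulation import HOURS_PER_WEEK
        from .pd_model import solve_pkpd

        records = []
        ds = self.model.dataset
        window = (0.0, window_weeks * HOURS_PER_WEEK)
        for sid, res in self.map_results.items():
            reg = ds.regimen_for(sid)
            times = np.linspace(0.0, max(reg.horizon, window[1]), 241)
            traj = solve_pkpd(reg, res.individual_params, times)
            nadir, last = psa_percent_changes(traj, res.individual_params.pd.PSA0_i,
                                              window)
            records.append(ExposureRecord(
                subject_id=sid, auc_tumor=tumor_auc(traj, window=window),
                pct_change_nadir=nadir, pct_change_last=last,
            ))
        ols = fit_exposure_response(records, endpoint=endpoint)
        intercept, slope = ols.params
        return {
            "records": records,
            "ols": ols,
            "slope": float(slope),
            "intercept": float(intercept),
            "threshold": auc_threshold(float(slope), float(intercept)),
        }

    def summary(self) -> str:
        lines = ["PKPD model fit", "=" * 46, f"method: {self.method}"]
        if self.method == "pooled":
            lines.append(f"n obs: {self.pooled.n_obs}  "
                         f"objective: {self.pooled.objective:.6g}")
            lines.append(f"{'parameter':<14}{'estimate':>14}{'approx SE':>14}")
            for name, est in self.pooled.estimates.items():
                lines.append(f"{name:<14}{est:>14.6g}{self.pooled.se[name]:>14.3g}")
        else:
            lines.append(f"subjects: {len(self.map_results)}")
            eta = self.eta
            lines.append("per-subject MAP eta (mean ± SD):")
            for col in eta.columns:
                lines.append(f"  {col:<12}{eta[col].mean():>10.4f} ± {eta[col].std():.4f}")
        return "\n".join(lines)
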
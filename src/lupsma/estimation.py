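"""Individual MAP (empirical-Bayes) estimation and naive-pooled fitting.

Full nonlinear mixed-effects estimation is out of scope; the estimation
surface here serves two purposes: (i) MAP estimation of individual random
effects given known population parameters — the Bayesian-forecasting use of
the model — and (ii) naive-pooled weighted least squares on event datasets,
used for parameter-recovery validation of the implemented equations.

Observations follow the event-record convention: the central compartment is
observed as a decay-corrected concentration (MBq/L), salivary glands,
kidneys and tumor as decay-corrected amounts (MBq, corrected to the most
recent injection), and PSA in µg/L.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .covariates import individualize
from .model_core import IDX_A1, IDX_A2, IDX_A3, IDX_A4, IDX_PSA
from .params import CovariateSet, PDParameters, PKParameters, VarianceParameters
from .pd_model import solve_pkpd
from .population import residual_models
from .simulation import Regimen, custom_regimen

logger = logging.getLogger(__name__)

CMT_CODES = {1: "central", 2: "salivary", 3: "kidneys", 4: "tumor", 6: "psa"}
CMT_UNITS = {"central": "MBq/L", "salivary": "MBq", "kidneys": "MBq",
             "tumor": "MBq", "psa": "ug/L"}
_CMT_STATE = {"central": IDX_A1, "salivary": IDX_A2, "kidneys": IDX_A3,
              "tumor": IDX_A4, "psa": IDX_PSA}

REQUIRED_COLUMNS = ["ID", "TIME", "EVID", "AMT", "CMT", "DV", "MDV", "WT", "TV", "CYCLE"]


@dataclass
class ObservationSet:
    """Typed view of a NONMEM-style event dataset."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        bad = set(self.data["CMT"].astype(int)) - set(CMT_CODES) - {0}
        if bad:
            rows = self.data.index[self.data["CMT"].isin(bad)].tolist()[:5]
            raise ValueError(f"unknown CMT codes {sorted(bad)} (rows {rows})")
        for sid, grp in self.data.groupby("ID"):
            t = grp["TIME"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                raise ValueError(f"non-monotone times within subject {sid}")

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.data["ID"]))

    def observations(self, subject_id=None) -> pd.DataFrame:
        df = self.data
        if subject_id is not None:
            df = df[df["ID"] == subject_id]
        return df[(df["EVID"] == 0) & (df["MDV"] == 0)]

    def doses(self, subject_id) -> pd.DataFrame:
        df = self.data
        return df[(df["ID"] == subject_id) & (df["EVID"] == 1)]

    def regimen_for(self, subject_id) -> Regimen:
        doses = self.doses(subject_id)
        obs = self.observations(subject_id)
        horizon = float(
            max(
                obs["TIME"].max() if len(obs) else 0.0,
                doses["TIME"].max() if len(doses) else 0.0,
            )
        ) + 1.0
        return custom_regimen(
            doses["TIME"].to_numpy(dtype=float),
            doses["AMT"].to_numpy(dtype=float),
            horizon=horizon,
        )

    def covariates_for(self, subject_id) -> CovariateSet:
        sub = self.data[self.data["ID"] == subject_id].iloc[0]
        return CovariateSet(WT=float(sub["WT"]), TV=float(sub["TV"]))


def decay_correct_amounts(
    values: np.ndarray,
    times: np.ndarray,
    dose_times: np.ndarray,
    lam: float,
    direction: str = "to_corrected",
) -> np.ndarray:
    """Convert physical amounts to per-cycle decay-corrected ones (or back).

    The correction reference for each time point is the most recent dose at
    or before it (or the first dose, for points preceding all doses).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(dose_times) == 0:
        ref = np.zeros_like(times)
    else:
        dose_times = np.sort(np.asarray(dose_times, dtype=float))
        idx = np.clip(np.searchsorted(dose_times, times, side="right") - 1, 0, None)
        ref = dose_times[idx]
    dt = np.maximum(times - ref, 0.0)
    if direction == "to_corrected":
        return values * np.exp(lam * dt)
    if direction == "to_physical":
        return values * np.exp(-lam * dt)
    raise ValueError(f"unknown direction {direction!r}")


def predict_observations(
    obs: pd.DataFrame,
    regimen: Regimen,
    individual_params,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Model predictions matching each observation row's time and compartment."""
    times = obs["TIME"].to_numpy(dtype=float)
    grid = np.unique(times)
    traj = solve_pkpd(regimen, individual_params, grid, rtol=rtol, atol=atol)
    lam = individual_params.pk_for_cycle(1).lambda_phys
    preds = np.empty(len(obs))
    for i, (_, row) in enumerate(obs.iterrows()):
        tag = CMT_CODES[int(row["CMT"])]
        t = float(row["TIME"])
        j = int(np.searchsorted(grid, t))
        val = traj.states[j, _CMT_STATE[tag]]
        if tag == "psa":
            preds[i] = val
            continue
        corr = decay_correct_amounts(
            np.array([val]), np.array([t]), traj.dose_times, lam
        )[0]
        if tag == "central":
            corr /= individual_params.pk_for_cycle(1).V1
        preds[i] = corr
    return preds


def _neg2ll(obs_values, preds, tags, sigmas) -> float:
    """−2·log-likelihood under the per-compartment residual error models."""
    total = 0.0
    for y, p, tag in zip(obs_values, preds, tags):
        var = float(sigmas[tag].variance(p))
        if var <= 0:
            if abs(y - p) > 1e-12 * max(1.0, abs(y)):
                logger.warning("zero residual variance with mismatching observation")
                return np.inf
            continue
        total += np.log(2.0 * np.pi * var) + (y - p) ** 2 / var
    return float(total)


def map_objective(
    eta: dict[str, float],
    observations: pd.DataFrame,
    regimen: Regimen,
    covariates: CovariateSet,
    params: PKParameters,
    pd_params: PDParameters,
    variances: VarianceParameters,
    iov_k14: list[float] | None = None,
    rtol: float = 1e-8,
) -> float:
    """Penalized deviance: −2LL of the data plus the η-prior penalty Σ η²/ω²."""
    penalty = 0.0
    for name, value in eta.items():
        omega = variances.omega(name)
        if omega <= 0:
            raise ValueError(f"omega for {name} must be > 0 to estimate its eta")
        penalty += (value / omega) ** 2
    if iov_k14 is not None:
        om = variances.omega_iov_k14
        if om <= 0:
            raise ValueError("omega_iov_k14 must be > 0 to estimate IOV")
        penalty += float(np.sum(np.square(np.asarray(iov_k14) / om)))
    ip = individualize(params, pd_params, covariates, eta, iov_k14,
                       max_cycles=max(regimen.n_cycles, 1))
    preds = predict_observations(observations, regimen, ip, rtol=rtol)
    tags = [CMT_CODES[int(c)] for c in observations["CMT"]]
    sigmas = residual_models(variances)
    return _neg2ll(observations["DV"].to_numpy(dtype=float), preds, tags, sigmas) + penalty


@dataclass
class MapResult:
    eta: dict[str, float]
    iov_k14: list[float] | None
    objective: float
    n_obs: int
    trace: list[float] = field(default_factory=list)
    individual_params: object = None


def map_estimate(
    observations: pd.DataFrame,
    regimen: Regimen,
    covariates: CovariateSet,
    params: PKParameters,
    pd_params: PDParameters,
    variances: VarianceParameters,
    eta_names: tuple[str, ...] = ("k10", "k13", "k14", "k15", "Bmax_sal"),
    estimate_iov: bool = False,
    n_starts: int = 3,
    rtol: float = 1e-8,
    xtol: float = 1e-6,
) -> MapResult:
    """Minimize the MAP objective over the named η's (multi-start).

    Returns the η estimates, per-cycle IOV estimates when requested, the
    objective value and the accepted-objective trace (monotone decreasing).
    """
    if len(observations) < 1:
        raise ValueError("at least one observation is required")
    n_occ = regimen.n_cycles if estimate_iov else 0
    dim = len(eta_names) + n_occ
    trace: list[float] = []
    best = None

    def unpack(x):
        eta = dict(zip(eta_names, x[: len(eta_names)]))
        iov = list(x[len(eta_names):]) if n_occ else None
        return eta, iov

    def fun(x):
        eta, iov = unpack(x)
        val = map_objective(eta, observations, regimen, covariates, params,
                            pd_params, variances, iov, rtol=rtol)
        if not trace or val < trace[-1]:
            trace.append(val)
        return val

    rng = np.random.default_rng(0)
    starts = [np.zeros(dim)]
    for _ in range(n_starts - 1):
        starts.append(rng.normal(0.0, 0.3, size=dim))
    for x0 in starts:
        res = optimize.minimize(
            fun, x0, method="Nelder-Mead",
            options={"xatol": xtol, "fatol": 1e-8, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("MAP optimization failed to produce a finite objective")
    eta, iov = unpack(best.x)
    ip = individualize(params, pd_params, covariates, eta, iov,
                       max_cycles=max(regimen.n_cycles, 1))
    return MapResult(eta=eta, iov_k14=iov, objective=float(best.fun),
                     n_obs=len(observations), trace=trace, individual_params=ip)


# ---------------------------------------------------------------------------
# naive-pooled fitting

_FRACTION_NAMES = ("cycle2", "cycle3", "cycle4_7")
_PD_NAMES = ("kG", "kD_direct", "ke0", "kD_delay")


def _apply_free(params: PKParameters, pd_params: PDParameters,
                free: dict[str, float]) -> tuple[PKParameters, PDParameters]:
    pk_kw: dict = {}
    pd_kw: dict = {}
    fractions = list(params.cycle_fractions)
    for name, value in free.items():
        if name in _FRACTION_NAMES:
            fractions[_FRACTION_NAMES.index(name)] = value
        elif name in _PD_NAMES:
            pd_kw[name] = value
        elif hasattr(params, name):
            pk_kw[name] = value
        else:
            raise ValueError(f"unknown free parameter {name!r}")
    pk_kw["cycle_fractions"] = tuple(fractions)
    return params.replace(**pk_kw), (pd_params.replace(**pd_kw) if pd_kw else pd_params)


@dataclass
class PooledFitResult:
    estimates: dict[str, float]
    objective: float
    n_obs: int
    se: dict[str, float]
    success: bool
    message: str = ""


def naive_pooled_fit(
    dataset: ObservationSet,
    free: list[str],
    start: dict[str, float] | None = None,
    params: PKParameters | None = None,
    pd_params: PDParameters | None = None,
    variances: VarianceParameters | None = None,
    rtol: float = 1e-8,
) -> PooledFitResult:
    """Weighted least squares on all subjects pooled, ignoring random effects.

    Free parameters are optimized on the log scale; the remaining structural
    parameters stay fixed at their supplied values (V1 in particular stays at
    its fixed population value).  Weights come from the per-compartment
    residual error models evaluated at the starting predictions.  Approximate
    standard errors come from the Jacobian at the optimum; with data that
    cannot inform a parameter (flat curvature) a warning is logged and the SE
    reported as inf.
    """
    params = params if params is not None else PKParameters()
    pd_params = pd_params if pd_params is not None else PDParameters()
    variances = variances if variances is not None else VarianceParameters()
    sigmas = residual_models(variances)

    defaults: dict[str, float] = {}
    for name in free:
        if name in _FRACTION_NAMES:
            defaults[name] = params.cycle_fractions[_FRACTION_NAMES.index(name)]
        elif name in _PD_NAMES:
            defaults[name] = getattr(pd_params, name)
        elif hasattr(params, name):
            defaults[name] = getattr(params, name)
        else:
            raise ValueError(f"unknown free parameter {name!r}")
    x0 = np.log([start.get(n, defaults[n]) if start else defaults[n] for n in free])

    subjects = dataset.subject_ids
    per_subject = []
    for sid in subjects:
        obs = dataset.observations(sid)
        if not len(obs):
            continue
        tags = [CMT_CODES[int(c)] for c in obs["CMT"]]
        per_subject.append((sid, obs, dataset.regimen_for(sid),
                            dataset.covariates_for(sid), tags))
    if not per_subject:
        raise ValueError("dataset contains no observations")

    # weights fixed at start predictions (iteratively reweighted once)
    def all_preds(theta_log):
        trial_pk, trial_pd = _apply_free(
            params, pd_params, dict(zip(free, np.exp(theta_log)))
        )
        chunks = []
        for sid, obs, regimen, cov, tags in per_subject:
            ip = individualize(trial_pk, trial_pd, cov,
                               max_cycles=max(regimen.n_cycles, 1))
            chunks.append(predict_observations(obs, regimen, ip, rtol=rtol))
        return np.concatenate(chunks)

    obs_all = np.concatenate([
        obs["DV"].to_numpy(dtype=float) for _, obs, _, _, _ in per_subject
    ])
    tags_all = [t for _, _, _, _, tags in per_subject for t in tags]
    base_preds = all_preds(x0)
    sd = np.sqrt([
        max(float(sigmas[tag].variance(p)), 1e-12)
        for tag, p in zip(tags_all, base_preds)
    ])

    def residuals(theta_log):
        return (obs_all - all_preds(theta_log)) / sd

    res = optimize.least_squares(
        residuals, x0, method="lm" if len(x0) <= len(obs_all) else "trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    estimates = dict(zip(free, np.exp(res.x)))
    # curvature diagnostics on the log scale
    J = res.jac
    se = {}
    try:
        cov_log = np.linalg.inv(J.T @ J)
        diag = np.clip(np.diag(cov_log), 0, None)
        for i, name in enumerate(free):
            se[name] = float(np.sqrt(diag[i]) * estimates[name])
    except np.linalg.LinAlgError:
        logger.warning("flat curvature: requested parameters are not identifiable "
                       "from this dataset")
        se = {name: float("inf") for name in free}
    return PooledFitResult(
        estimates=estimates,
        objective=float(np.sum(res.fun ** 2)),
        n_obs=len(obs_all),
        se=se,
        success=bool(res.success),
        message=str(res.message),
    )
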
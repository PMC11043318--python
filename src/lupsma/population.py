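"""Random-effect sampling, the box-cox η transform and residual error models.

Inter-individual variability enters parameters as ``P_i = P_pop·exp(η_i)``
with η ~ N(0, ω²); inter-occasion variability on the tumor uptake rate is
redrawn per treatment cycle.  Reported coefficients of variation (CV%) are
converted to ω by the common reporting approximation ω = CV/100; the exact
lognormal relation ω = sqrt(ln(1 + CV²)) is available behind a flag — for
the very large PD CVs the two differ materially in the tails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import VarianceParameters


def cv_to_omega(cv_percent: float, convention: str = "direct") -> float:
    """Standard deviation ω of η from a reported CV%."""
    if cv_percent < 0:
        raise ValueError("CV% must be >= 0")
    cv = cv_percent / 100.0
    if convention == "direct":
        return cv
    if convention == "lognormal_exact":
        return math.sqrt(math.log1p(cv * cv))
    raise ValueError(f"unknown CV convention {convention!r}")


def boxcox_eta(eta: float, shape: float) -> float:
    """Box-cox transform of a normal random effect.

    η* = ((e^η)^θ − 1)/θ, reducing to the identity as θ → 0.  For θ < 0 the
    transform is bounded above by −1/θ, which skews the individual
    multiplier distribution toward values below the typical one.
    """
    if abs(shape) < 1e-8:
        return float(eta)
    return float((math.exp(eta * shape) - 1.0) / shape)


def sample_random_effects(
    variances: VarianceParameters,
    n_subjects: int,
    n_occasions: int,
    seed: int | np.random.Generator,
) -> list[dict]:
    """Draw independent η vectors (plus per-occasion IOV) for n subjects.

    Returns one dict per subject: keys are the η names of
    :class:`VarianceParameters` plus ``iov_k14`` (array of length
    n_occasions).  No correlation structure is applied.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        eta = {
            name: float(rng.normal(0.0, variances.omega(name)))
            if variances.omega(name) > 0 else 0.0
            for name in VarianceParameters.ETA_NAMES
        }
        iov = (
            rng.normal(0.0, variances.omega_iov_k14, size=n_occasions)
            if variances.omega_iov_k14 > 0
            else np.zeros(n_occasions)
        )
        eta["iov_k14"] = np.asarray(iov, dtype=float)
        out.append(eta)
    return out


@dataclass(frozen=True)
class ResidualErrorModel:
    """Observation-level error: combined (central) or proportional.

    combined:      C_obs = C_pred·(1 + ε_p) + ε_add
    proportional:  C_obs = C_pred·(1 + ε_p)
    """

    kind: str = "proportional"
    sigma_prop: float = 0.0
    sigma_add: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("combined", "proportional"):
            raise ValueError(f"unknown residual error kind {self.kind!r}")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("sigma values must be >= 0")

    def variance(self, pred: float | np.ndarray) -> float | np.ndarray:
        v = (self.sigma_prop * np.asarray(pred, dtype=float)) ** 2
        if self.kind == "combined":
            v = v + self.sigma_add ** 2
        return v


def apply_residual_error(
    pred: float | np.ndarray,
    model: ResidualErrorModel,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Perturb predictions with the residual error model.

    The combined model can yield negative observations at low predictions,
    mirroring the negative early blood concentrations that quantitative
    SPECT produces after the blood correction.
    """
    pred = np.atleast_1d(np.asarray(pred, dtype=float))
    if not np.all(np.isfinite(pred)):
        raise ValueError("predictions must be finite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps_p = rng.normal(0.0, model.sigma_prop, size=pred.shape) if model.sigma_prop > 0 else 0.0
    obs = pred * (1.0 + eps_p)
    if model.kind == "combined" and model.sigma_add > 0:
        obs = obs + rng.normal(0.0, model.sigma_add, size=pred.shape)
    return obs


def residual_models(variances: VarianceParameters) -> dict[str, ResidualErrorModel]:
    """Per-compartment residual models from a variance parameter set."""
    return {
        "central": ResidualErrorModel(
            "combined", variances.sigma_prop_central, variances.sigma_add_central
        ),
        "salivary": ResidualErrorModel("proportional", variances.sigma_prop_salivary),
        "kidneys": ResidualErrorModel("proportional", variances.sigma_prop_kidneys),
        "tumor": ResidualErrorModel("proportional", variances.sigma_prop_tumor),
        "psa": ResidualErrorModel("proportional", variances.sigma_prop_psa),
    }
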
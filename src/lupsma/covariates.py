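"""Covariate functions, allometric scaling and parameter individualization.

The retained covariate effects are: a power function of segmented tumor
volume on the tumor uptake rate k14 (exponent 1.08) and on the salivary
uptake rate k12 (tumor sink, exponent 0.0910); a linear tumor-volume term on
baseline PSA; allometric body-weight scaling on all rate constants
(exponent −0.25) and the central volume (exponent 1); and a structural
attenuation of k14 in later treatment cycles.  Renal function (GFR) was
evaluated and rejected, so it never enters any calculation.
"""

from __future__ import annotations

import logging
import math

from .model_core import IndividualParameters
from .params import CovariateSet, PDParameters, PKParameters, Subject
from .population import boxcox_eta

logger = logging.getLogger(__name__)


def covariate_factor(
    form: str,
    P_pop: float,
    theta_cov: float,
    cov: float,
    cov_median: float,
) -> float:
    """Adjusted parameter value under a power, linear or exponential covariate.

    power:        P·(cov/median)^θ
    linear:       P + θ·(cov/median)
    exponential:  P·exp(θ·(cov/median))
    """
    if cov_median <= 0:
        raise ValueError("cov_median must be > 0")
    ratio = cov / cov_median
    if form == "power":
        if cov <= 0:
            raise ValueError("power covariate requires cov > 0")
        return P_pop * ratio ** theta_cov
    if form == "linear":
        return P_pop + theta_cov * ratio
    if form == "exponential":
        return P_pop * math.exp(theta_cov * ratio)
    raise ValueError(f"unknown covariate form {form!r}")


def cycle_effect(
    k14_base: float,
    cycle_index: int,
    cycle_fractions: tuple[float, float, float],
) -> float:
    """Tumor uptake rate for a given treatment cycle.

    Cycle 1 keeps the population value; cycles 2 and 3 are attenuated to the
    given fractions; cycles 4–7 share a single fraction.  Cycles beyond 7
    reuse the 4–7 fraction (with a warning) — later cycles were too sparse to
    resolve separately.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index must be >= 1")
    if cycle_index == 1:
        return k14_base
    if cycle_index == 2:
        return k14_base * cycle_fractions[0]
    if cycle_index == 3:
        return k14_base * cycle_fractions[1]
    if cycle_index > 7:
        logger.warning(
            "cycle_index %d beyond 7; reusing the cycle 4-7 fraction", cycle_index
        )
    return k14_base * cycle_fractions[2]


def allometric_scale(params: PKParameters, WT: float, WT_median: float | None = None) -> PKParameters:
    """Scale all rate constants and V1 by body weight.

    Rates scale with (WT/median)^−0.25, the central volume with (WT/median)^1.
    The salivary binding capacity B_MAX is a receptor amount, not a rate or a
    volume, and is left unscaled.
    """
    if WT <= 0:
        raise ValueError("body weight must be > 0")
    ref = params.WT_median if WT_median is None else WT_median
    ratio = WT / ref
    fk = ratio ** params.allometric_exponent_k
    fv = ratio ** params.allometric_exponent_V
    return params.replace(
        **{name: getattr(params, name) * fk for name in PKParameters.RATE_NAMES},
        V1=params.V1 * fv,
    )


class IndividualPDParameters:
    """PD parameter set finalized for one subject."""

    def __init__(
        self,
        PSA0_i: float,
        kG: float,
        kD_direct_h: float,
        ke0: float,
        kD_delay_h: float,
        form: str = "linear",
        EMAX: float | None = None,
        EC50: float | None = None,
        gamma: float = 1.0,
    ) -> None:
        self.PSA0_i = PSA0_i
        self.kG = kG
        self.kD_direct_h = kD_direct_h
        self.ke0 = ke0
        self.kD_delay_h = kD_delay_h
        self.form = form
        self.EMAX = EMAX
        self.EC50 = EC50
        self.gamma = gamma


def baseline_psa(pd: PDParameters, cov: CovariateSet, TV_median: float) -> float:
    """Typical baseline PSA after the tumor-volume covariate.

    The default ('literal') form is PSA0 + θ·(TV/TV_median); the alternative
    'centered' form PSA0 + θ·(TV/TV_median − 1) returns the fixed typical
    value at the median tumor volume.
    """
    ratio = cov.TV / TV_median
    if pd.baseline_covariate_form == "centered":
        return pd.PSA0 + pd.theta_TV_PSA0 * (ratio - 1.0)
    return covariate_factor("linear", pd.PSA0, pd.theta_TV_PSA0, cov.TV, TV_median)


def individualize(
    params: PKParameters,
    pd: PDParameters,
    cov: CovariateSet,
    eta: dict[str, float] | None = None,
    iov_k14: "list[float] | None" = None,
    max_cycles: int = 8,
) -> IndividualParameters:
    """Produce the per-cycle individual parameter set for one subject.

    Factors on k14 apply multiplicatively in the order: population value →
    tumor-volume power covariate → allometric scaling → exp(η_IIV) →
    exp(η_IOV, per occasion) → cycle-effect fraction.  k_G receives a
    box-cox-transformed η; baseline PSA receives the linear tumor-volume
    covariate and then exp(η).
    """
    eta = eta or {}
    unknown = set(eta) - {f"eta_{n}" for n in ("k10", "k13", "k14", "k15", "Bmax_sal",
                                               "PSA0", "kG", "kDdirect", "kDdelay")} \
        - {"k10", "k13", "k14", "k15", "Bmax_sal", "PSA0", "kG", "kDdirect", "kDdelay"}
    if unknown:
        raise ValueError(f"unknown random-effect names: {sorted(unknown)}")

    def get(name: str) -> float:
        return eta.get(name, eta.get(f"eta_{name}", 0.0))

    # tumor-volume covariates (power)
    k12_cov = covariate_factor("power", params.k12, params.theta_TV_k12, cov.TV, params.TV_median)
    k14_cov = covariate_factor("power", params.k14, params.theta_TV_k14, cov.TV, params.TV_median)
    base = params.replace(k12=k12_cov, k14=k14_cov)
    # allometric body-weight scaling on all rates and V1
    base = allometric_scale(base, cov.WT)
    # IIV
    base = base.replace(
        k10=base.k10 * math.exp(get("k10")),
        k13=base.k13 * math.exp(get("k13")),
        k14=base.k14 * math.exp(get("k14")),
        k15=base.k15 * math.exp(get("k15")),
        B_MAX_sal=base.B_MAX_sal * math.exp(get("Bmax_sal")),
    )

    pk_by_cycle = []
    for cycle in range(1, max_cycles + 1):
        k14_c = base.k14
        if iov_k14 is not None and len(iov_k14) >= cycle:
            k14_c *= math.exp(iov_k14[cycle - 1])
        k14_c = cycle_effect(k14_c, cycle, params.cycle_fractions)
        k12_c = base.k12
        if params.salivary_cycle_fractions is not None:
            # optional scenario: attenuated salivary uptake in cycles 2-3
            if cycle == 2:
                k12_c *= params.salivary_cycle_fractions[0]
            elif cycle == 3:
                k12_c *= params.salivary_cycle_fractions[1]
        pk_by_cycle.append(base.replace(k14=k14_c, k12=k12_c))

    psa0_i = baseline_psa(pd, cov, params.TV_median) * math.exp(get("PSA0"))
    kG_i = pd.kG * math.exp(boxcox_eta(get("kG"), pd.boxcox_shape))
    ipd = IndividualPDParameters(
        PSA0_i=psa0_i,
        kG=kG_i,
        kD_direct_h=pd.kD_direct_h * math.exp(get("kDdirect")),
        ke0=pd.ke0,
        kD_delay_h=pd.kD_delay_h * math.exp(get("kDdelay")),
        form=pd.drug_effect_form,
        EMAX=pd.EMAX,
        EC50=pd.EC50,
        gamma=pd.gamma,
    )
    return IndividualParameters(
        pk_by_cycle=pk_by_cycle,
        pd=ipd,
        tumor_volume=cov.TV,
        body_weight=cov.WT,
    )


def individualize_subject(
    params: PKParameters, pd: PDParameters, subject: Subject, max_cycles: int = 8
) -> IndividualParameters:
    iov = list(subject.iov_k14) if len(subject.iov_k14) else None
    return individualize(params, pd, subject.covariates, subject.eta, iov, max_cycles)
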
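"""PSA dynamics: exponential growth, direct and delayed drug effects.

Serum PSA grows exponentially at rate k_G and is eliminated by two
treatment-driven terms, both proportional to PSA:

    dPSA/dt = (k_G − E_drug − E_delayed) · PSA

E_drug acts on the instantaneous (physical, decay-inclusive) tumor activity
concentration; E_delayed acts on an effect-compartment level Ce that
equilibrates with the tumor concentration at first-order rate ke0,

    dCe/dt = ke0 · (C_tumor − Ce),

producing the continued PSA decline observed after the activity has washed
out.  The coupling is sequential and one-directional: PK states drive PSA,
never the reverse.  No drug effect applies before the first administration.
"""

from __future__ import annotations

import numpy as np

from .covariates import IndividualPDParameters
from .model_core import IndividualParameters, TrajectoryRecord, solve_pk


def drug_effect(form: str, C_tumor: float, pd) -> float:
    """Direct elimination-rate contribution (h⁻¹) from tumor concentration.

    linear:   kD·C          (the final model)
    emax:     EMAX·C/(EC50 + C)
    sigmoid:  EMAX·C^γ/(EC50^γ + C^γ)
    """
    if C_tumor < 0:
        raise ValueError("C_tumor must be >= 0")
    if form == "linear":
        return pd.kD_direct_h * C_tumor
    if form in ("emax", "sigmoid"):
        if pd.EC50 is None or pd.EC50 <= 0:
            raise ValueError("emax/sigmoid forms require EC50 > 0")
        if pd.EMAX is None:
            raise ValueError("emax/sigmoid forms require EMAX")
        gamma = pd.gamma if form == "sigmoid" else 1.0
        cg = C_tumor ** gamma
        return pd.EMAX * cg / (pd.EC50 ** gamma + cg)
    raise ValueError(f"unknown drug effect form {form!r}")


def delayed_effect(Ce: float, pd) -> float:
    """Delayed elimination-rate contribution kD_delay·Ce (h⁻¹, linear form)."""
    return pd.kD_delay_h * Ce


def pd_rhs(
    psa: float,
    Ce: float,
    C_tumor: float,
    pd: IndividualPDParameters,
    drug_active: bool = True,
) -> tuple[float, float]:
    """(dCe/dt, dPSA/dt) given the instantaneous tumor concentration."""
    if psa <= 0:
        raise ValueError("PSA must be > 0")
    if not drug_active:
        return 0.0, pd.kG * psa
    dCe = pd.ke0 * (C_tumor - Ce)
    e = drug_effect(pd.form, C_tumor, pd) + delayed_effect(Ce, pd)
    return dCe, (pd.kG - e) * psa


def solve_pkpd(
    regimen,
    individual_params: IndividualParameters,
    times: np.ndarray,
    decay_mode: str = "physical",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TrajectoryRecord:
    """Joint PK/PD integration of one subject across a regimen."""
    if individual_params.pd is None:
        raise ValueError("individual parameter set has no PD component")
    return solve_pk(
        regimen,
        individual_params,
        times,
        decay_mode=decay_mode,
        rtol=rtol,
        atol=atol,
        with_pd=True,
    )
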
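"""Parameter containers for the PK and PD sub-models.

All rate constants are in h⁻¹ and amounts in MBq internally.  The direct and
delayed PSA kill coefficients are reported in the literature in
L·day⁻¹·GBq⁻¹ and L·day⁻¹·MBq⁻¹ respectively; they are stored here as
reported and converted on access (``kD_direct_h``, ``kD_delay_h``) so that
``kD * C_tumor`` with ``C_tumor`` in MBq/L yields an elimination rate in h⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Physical half-life of 177Lu in hours (6.647 days).
LU177_HALF_LIFE_H = 159.528

#: Physical decay constant of 177Lu (h^-1).
LAMBDA_PHYS = math.log(2.0) / LU177_HALF_LIFE_H

#: Real-cohort tumor time-integrated-activity thresholds (MBq·h/mL) reported
#: for a >=50% PSA decrease at nadir and at the last observation after the
#: first two cycles.  Documented reference values only: they derive from
#: patient data that is not redistributable, so the package never recomputes
#: or asserts them.
REFERENCE_AUC_THRESHOLD_NADIR = 709.5
REFERENCE_AUC_THRESHOLD_LAST = 1188.0


@dataclass(frozen=True)
class PKParameters:
    """Fixed effects of the five-compartment radioligand kinetic model.

    Compartments: 1 central (blood), 2 salivary glands, 3 kidneys, 4 tumor
    (all segmented lesions lumped), 5 remaining tissues.  Uptake into the
    salivary glands saturates with capacity ``B_MAX_sal``; all other
    transfers are first order.
    """

    k10: float = 0.253
    k12: float = 0.0105
    k21: float = 0.0629
    k13: float = 0.0321
    k31: float = 0.0625
    k14: float = 0.00967
    k41: float = 0.0150
    k15: float = 0.275
    k51: float = 0.0247
    B_MAX_sal: float = 134.0
    V1: float = 10.3
    theta_TV_k12: float = 0.0910
    theta_TV_k14: float = 1.08
    cycle_fractions: tuple[float, float, float] = (0.731, 0.498, 0.436)
    WT_median: float = 79.0
    TV_median: float = 0.0443
    lambda_phys: float = LAMBDA_PHYS
    allometric_exponent_k: float = -0.25
    allometric_exponent_V: float = 1.0
    salivary_cycle_fractions: tuple[float, float] | None = None

    RATE_NAMES = ("k10", "k12", "k21", "k13", "k31", "k14", "k41", "k15", "k51")

    def __post_init__(self) -> None:
        for name in self.RATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if self.V1 <= 0:
            raise ValueError("V1 must be > 0")
        if self.B_MAX_sal <= 0:
            raise ValueError("B_MAX_sal must be > 0")
        if self.lambda_phys <= 0:
            raise ValueError("lambda_phys must be > 0")
        for f in self.cycle_fractions:
            if not 0.0 < f <= 1.0:
                raise ValueError("cycle fractions must lie in (0, 1]")

    def replace(self, **kwargs) -> "PKParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PDParameters:
    """Fixed effects of the PSA dynamics model.

    PSA grows exponentially at ``kG`` and is eliminated by a direct effect
    proportional to the tumor activity concentration and a delayed effect
    proportional to an effect-compartment level equilibrating at ``ke0``.
    The final model uses linear forms for both effects; Emax and sigmoid
    Emax alternatives are selectable for the direct effect.
    """

    PSA0: float = 140.0
    theta_TV_PSA0: float = 57.5
    kG: float = 0.000408
    kD_direct: float = 0.00335      # L/day/GBq as reported
    ke0: float = 0.00128
    kD_delay: float = 0.0000328     # L/day/MBq as reported
    boxcox_shape: float = -0.822
    EMAX: float | None = None
    EC50: float | None = None
    gamma: float = 1.0
    drug_effect_form: str = "linear"
    baseline_covariate_form: str = "literal"   # or "centered"

    def __post_init__(self) -> None:
        if self.kG <= 0:
            raise ValueError("kG must be > 0")
        for name in ("PSA0", "theta_TV_PSA0", "kD_direct", "ke0", "kD_delay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.drug_effect_form not in ("linear", "emax", "sigmoid"):
            raise ValueError(f"unknown drug effect form {self.drug_effect_form!r}")
        if self.baseline_covariate_form not in ("literal", "centered"):
            raise ValueError(
                f"unknown baseline covariate form {self.baseline_covariate_form!r}"
            )

    @property
    def kD_direct_h(self) -> float:
        """Direct kill coefficient in (MBq/L)⁻¹·h⁻¹ (from L·day⁻¹·GBq⁻¹)."""
        return self.kD_direct / 24.0 / 1000.0

    @property
    def kD_delay_h(self) -> float:
        """Delayed kill coefficient in (MBq/L)⁻¹·h⁻¹ (from L·day⁻¹·MBq⁻¹)."""
        return self.kD_delay / 24.0

    def replace(self, **kwargs) -> "PDParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class VarianceParameters:
    """Random-effect standard deviations (ω) and residual error magnitudes.

    ``omega_*`` values are standard deviations of normally distributed η's
    (Coefficient-of-variation percentages from the reporting convention are
    converted via :func:`lupsma.population.cv_to_omega`).
    """

    omega_k10: float = 0.331
    omega_k13: float = 0.334
    omega_k14: float = 0.634
    omega_k15: float = 0.291
    omega_Bmax_sal: float = 0.670
    omega_iov_k14: float = 0.378
    omega_PSA0: float = 1.79
    omega_kG: float = 0.909
    omega_kDdirect: float = 1.40
    omega_kDdelay: float = 0.875
    sigma_prop_central: float = 0.555
    sigma_add_central: float = 9.57
    sigma_prop_salivary: float = 0.397
    sigma_prop_kidneys: float = 0.319
    sigma_prop_tumor: float = 0.327
    sigma_prop_psa: float = 0.293

    ETA_NAMES = (
        "k10", "k13", "k14", "k15", "Bmax_sal",
        "PSA0", "kG", "kDdirect", "kDdelay",
    )

    def omega(self, name: str) -> float:
        return getattr(self, f"omega_{name}")

    def replace(self, **kwargs) -> "VarianceParameters":
        return replace(self, **kwargs)

    @classmethod
    def zeroed(cls) -> "VarianceParameters":
        """All ω and σ set to zero (typical-subject, noise-free regime)."""
        import dataclasses

        return cls(**{f.name: 0.0 for f in dataclasses.fields(cls)})


@dataclass(frozen=True)
class CovariateSet:
    """Per-subject covariates.

    GFR is carried for completeness but has no effect on any model output:
    renal function was evaluated as a covariate on the excretion rate and
    rejected.
    """

    WT: float = 79.0
    TV: float = 0.0443
    GFR: float | None = None

    def __post_init__(self) -> None:
        if self.WT <= 0:
            raise ValueError("body weight must be > 0")
        if self.TV <= 0:
            raise ValueError("tumor volume must be > 0")


@dataclass
class Subject:
    """A virtual or real subject: covariates plus sampled random effects."""

    id: int
    covariates: CovariateSet
    eta: dict[str, float] = field(default_factory=dict)
    iov_k14: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def eta_value(self, name: str) -> float:
        return self.eta.get(name, 0.0)

    def iov_value(self, occasion: int) -> float:
        """IOV η for a 1-based occasion (treatment cycle)."""
        idx = occasion - 1
        if 0 <= idx < len(self.iov_k14):
            return float(self.iov_k14[idx])
        return 0.0
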
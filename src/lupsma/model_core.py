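"""Structural five-compartment kinetic model and derived quantities.

The state vector is ``[A1, A2, A3, A4, A5, Ce, PSA]``: radioactivity amounts
(MBq) in central blood, salivary glands, kidneys, tumor and remaining
tissues, the effect-compartment exposure level (MBq/L) and serum PSA (µg/L).

Two decay conventions are supported.  In ``physical`` mode (the canonical
internal mode) the physical decay constant of 177Lu is applied uniformly to
all five activity compartments, so amounts are the physically present
activity at time t.  In ``corrected`` mode no decay loss is applied and the
amounts correspond to data that have been decay-corrected back to the
injection time, which is how quantitative SPECT data are usually reported.
The transfer rate constants are the same in both modes: they describe the
biological kinetics estimated on decay-corrected data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .params import LAMBDA_PHYS as LAMBDA_PHYS_DEFAULT
from .params import PKParameters

N_STATES = 7
IDX_A1, IDX_A2, IDX_A3, IDX_A4, IDX_A5, IDX_CE, IDX_PSA = range(N_STATES)

COMPARTMENT_LABELS = {
    1: "central",
    2: "salivary",
    3: "kidneys",
    4: "tumor",
    5: "remaining",
}


@dataclass
class IndividualParameters:
    """Finalized per-subject parameters: one PK set per cycle plus PD."""

    pk_by_cycle: list  # list[PKParameters], index 0 = cycle 1
    pd: object | None = None  # IndividualPDParameters, set by covariate engine
    tumor_volume: float = 0.0443
    body_weight: float = 79.0

    def pk_for_cycle(self, cycle_index: int) -> PKParameters:
        if cycle_index < 1:
            raise ValueError("cycle_index must be >= 1")
        idx = min(cycle_index, len(self.pk_by_cycle)) - 1
        return self.pk_by_cycle[idx]


@dataclass
class TrajectoryRecord:
    """Solved state over time for one subject under one regimen."""

    times: np.ndarray
    states: np.ndarray          # shape (n_times, 7)
    decay_mode: str = "physical"
    tumor_volume: float = 0.0443
    subject_id: int | None = None
    dose_times: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def A1(self) -> np.ndarray:
        return self.states[:, IDX_A1]

    @property
    def A2(self) -> np.ndarray:
        return self.states[:, IDX_A2]

    @property
    def A3(self) -> np.ndarray:
        return self.states[:, IDX_A3]

    @property
    def A4(self) -> np.ndarray:
        return self.states[:, IDX_A4]

    @property
    def A5(self) -> np.ndarray:
        return self.states[:, IDX_A5]

    @property
    def Ce(self) -> np.ndarray:
        return self.states[:, IDX_CE]

    @property
    def psa(self) -> np.ndarray:
        return self.states[:, IDX_PSA]

    @property
    def tumor_conc(self) -> np.ndarray:
        """Tumor activity concentration (MBq/L) in the trajectory's own mode."""
        return self.A4 / self.tumor_volume

    def value_at(self, t: float, column: int) -> float:
        if t < self.times[0] - 1e-9 or t > self.times[-1] + 1e-9:
            raise ValueError(f"time {t} h outside solved range")
        return float(np.interp(t, self.times, self.states[:, column]))

    def psa_at(self, t: float) -> float:
        return self.value_at(t, IDX_PSA)


def pk_rhs(state: np.ndarray, p: PKParameters, decay_mode: str = "physical") -> np.ndarray:
    """Time derivative of the five activity compartments.

    Uptake into the salivary glands saturates: the central→salivary flux is
    ``k12·A1·(1 − A2/B_MAX)`` so that capacity-limited binding slows both
    the loss from blood and the gain in the gland.  All other transfers are
    first order.  Mass leaves the system only through renal excretion (k10)
    and, in physical mode, radioactive decay.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state[:5] < 0):
        raise ValueError("negative compartment amounts are not physical")
    if p.B_MAX_sal == 0:
        raise ValueError("B_MAX_sal must be nonzero")
    lam = p.lambda_phys if decay_mode == "physical" else 0.0
    A1, A2, A3, A4, A5 = state[:5]
    sat = 1.0 - A2 / p.B_MAX_sal
    flux12 = p.k12 * A1 * sat
    dA1 = (
        -(p.k10 + p.k13 + p.k14 + p.k15) * A1
        - flux12
        + p.k21 * A2 + p.k31 * A3 + p.k41 * A4 + p.k51 * A5
        - lam * A1
    )
    dA2 = flux12 - p.k21 * A2 - lam * A2
    dA3 = p.k13 * A1 - p.k31 * A3 - lam * A3
    dA4 = p.k14 * A1 - p.k41 * A4 - lam * A4
    dA5 = p.k15 * A1 - p.k51 * A5 - lam * A5
    out = np.zeros(N_STATES)
    out[:5] = (dA1, dA2, dA3, dA4, dA5)
    return out


def _full_rhs(t: float, y: np.ndarray, p: PKParameters, pd, tumor_volume: float,
              decay_mode: str, drug_active: bool) -> np.ndarray:
    """PK derivatives plus (optionally) effect-compartment and PSA dynamics."""
    lam = p.lambda_phys if decay_mode == "physical" else 0.0
    A1, A2, A3, A4, A5, Ce, PSA = y
    sat = 1.0 - A2 / p.B_MAX_sal
    flux12 = p.k12 * A1 * sat
    dA1 = (
        -(p.k10 + p.k13 + p.k14 + p.k15 + lam) * A1
        - flux12
        + p.k21 * A2 + p.k31 * A3 + p.k41 * A4 + p.k51 * A5
    )
    dA2 = flux12 - (p.k21 + lam) * A2
    dA3 = p.k13 * A1 - (p.k31 + lam) * A3
    dA4 = p.k14 * A1 - (p.k41 + lam) * A4
    dA5 = p.k15 * A1 - (p.k51 + lam) * A5
    if pd is None:
        return np.array([dA1, dA2, dA3, dA4, dA5, 0.0, 0.0])
    # physical tumor concentration drives the drug effect; clamp tiny
    # negative excursions from the solver's trial steps
    c_tum = max(A4, 0.0) / tumor_volume
    if decay_mode == "corrected":
        c_tum *= math.exp(-p.lambda_phys * t)
    Ce = max(Ce, 0.0)
    dCe = pd.ke0 * (c_tum - Ce) if drug_active else 0.0
    if drug_active:
        from .pd_model import drug_effect, delayed_effect

        e_drug = drug_effect(pd.form, c_tum, pd)
        e_del = delayed_effect(Ce, pd)
    else:
        e_drug = 0.0
        e_del = 0.0
    dPSA = (pd.kG - e_drug - e_del) * PSA
    return np.array([dA1, dA2, dA3, dA4, dA5, dCe, dPSA])


def solve_pk(
    regimen,
    individual_params: IndividualParameters,
    times: np.ndarray,
    decay_mode: str = "physical",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    with_pd: bool = False,
    psa0: float | None = None,
) -> TrajectoryRecord:
    """Integrate the kinetic system across a dosing regimen.

    Integration restarts at every dose event; the central amount jumps by
    the administered activity while all other states are continuous.
    Per-cycle parameters (cycle effect on tumor uptake, inter-occasion
    variability) switch at dose events.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("output times must be nondecreasing")
    dose_times = np.array([ev.time for ev in regimen.dose_events])
    if len(dose_times) > 1 and np.any(np.diff(dose_times) <= 0):
        raise ValueError("dose times must be strictly increasing")

    pd = individual_params.pd if with_pd else None
    y = np.zeros(N_STATES)
    if with_pd:
        if psa0 is None:
            psa0 = pd.PSA0_i
        # PSA0 is the baseline at the first administration; for earlier times
        # pure exponential growth is back-extrapolated
        t_anchor = dose_times[0] if len(dose_times) else times[0]
        t_start = min(times[0], t_anchor)
        y[IDX_PSA] = psa0 * math.exp(pd.kG * (t_start - t_anchor))

    # segment boundaries: start, each dose, end
    t0 = min(times[0], dose_times[0]) if len(dose_times) else times[0]
    t_end = times[-1]
    boundaries = [t0] + [t for t in dose_times if t0 < t <= t_end] + [t_end]
    # deduplicate while preserving order
    bounds: list[float] = []
    for b in boundaries:
        if not bounds or b > bounds[-1] + 1e-12:
            bounds.append(b)

    out = np.zeros((len(times), N_STATES))
    filled = np.zeros(len(times), dtype=bool)
    any_dose_given = False
    current_cycle = 0

    # handle observation times exactly at t0
    at_start = np.isclose(times, bounds[0])

    for seg_idx in range(len(bounds) - 1):
        a, b = bounds[seg_idx], bounds[seg_idx + 1]
        # apply any dose at segment start
        for ev in regimen.dose_events:
            if abs(ev.time - a) < 1e-9:
                y[IDX_A1] += ev.activity
                current_cycle = ev.cycle_index
                if ev.activity > 0:
                    any_dose_given = True
        if seg_idx == 0:
            out[at_start] = y
            filled |= at_start
        pk = individual_params.pk_for_cycle(max(current_cycle, 1))
        mask = (times > a + 1e-12) & (times <= b + 1e-12) & ~filled
        t_eval = times[mask]
        seg_eval = np.unique(np.concatenate([t_eval, [b]]))
        drug_active = any_dose_given
        sol = solve_ivp(
            _full_rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=seg_eval,
            rtol=rtol,
            atol=atol,
            args=(pk, pd, individual_params.tumor_volume, decay_mode, drug_active),
        )
        if not sol.success:
            raise RuntimeError(
                f"ODE solver failed in segment [{a}, {b}] h: {sol.message}"
            )
        if len(t_eval):
            idx = np.searchsorted(seg_eval, t_eval)
            out[mask] = sol.y[:, idx].T
            filled |= mask
        y = sol.y[:, -1].copy()

    return TrajectoryRecord(
        times=times,
        states=out,
        decay_mode=decay_mode,
        tumor_volume=individual_params.tumor_volume,
        dose_times=dose_times,
    )


def effective_half_life(k_out: float) -> float:
    """Biological half-life ln(2)/k_out of a first-order washout (h)."""
    if k_out <= 0:
        raise ValueError("k_out must be > 0")
    return math.log(2.0) / k_out


def renal_clearance(params: PKParameters) -> float:
    """Renal clearance k10·V1 in L/h."""
    return params.k10 * params.V1


def tumor_concentration(
    A4: float | np.ndarray,
    tumor_volume: float,
    t_abs: float | np.ndarray = 0.0,
    decay_mode: str = "physical",
    lambda_phys: float | None = None,
) -> float | np.ndarray:
    """Physical tumor activity concentration in MBq/L.

    With ``decay_mode='physical'`` the amount already includes decay and the
    concentration is simply A4/V.  With decay-corrected amounts the physical
    decay factor e^(−λ·t) is reapplied, ``t_abs`` being the time since the
    correction reference (injection).
    """
    if tumor_volume <= 0:
        raise ValueError("tumor_volume must be > 0")
    lam = LAMBDA_PHYS_DEFAULT if lambda_phys is None else lambda_phys
    conc = np.asarray(A4, dtype=float) / tumor_volume
    if decay_mode == "corrected":
        conc = conc * np.exp(-lam * np.asarray(t_abs, dtype=float))
    if np.ndim(conc) == 0:
        return float(conc)
    return conc
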
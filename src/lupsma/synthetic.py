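"""Study-like synthetic dataset generation.

Emulates the data-collection process of the clinical cohort: per cycle,
quantitative SPECT observations of blood (MBq/L), salivary glands, kidneys
and tumor (MBq) at roughly 4.6 h, 23.8 h and 6.8 days post injection, and
PSA series before/during/after treatment.  All emitted radioactivity values
are decay-corrected to the most recent injection, as quantitative SPECT data
are reported.  Blood values additionally pass through the SPECT-blood
measurement chain (a linear raw↔corrected map with intercept 6.27 MBq/L and
slope 0.828), whose inversion can produce negative early concentrations;
the study filter drops those rows.

Output is a NONMEM-style event table: ID, TIME (h since first dose),
EVID (1 dose / 0 observation), AMT (MBq), CMT (1 central, 2 salivary,
3 kidneys, 4 tumor, 6 PSA), DV, MDV, WT, TV, CYCLE, OCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import individualize_subject
from .estimation import ObservationSet, decay_correct_amounts
from .model_core import IDX_A1, IDX_A2, IDX_A3, IDX_A4
from .params import PDParameters, PKParameters, VarianceParameters
from .pd_model import solve_pkpd
from .population import residual_models
from .simulation import HOURS_PER_WEEK, Regimen, VirtualPopulation

BLOOD_CORRECTION_INTERCEPT = 6.27   # MBq/L
BLOOD_CORRECTION_SLOPE = 0.828

_CMT_BY_STATE = [(1, IDX_A1), (2, IDX_A2), (3, IDX_A3), (4, IDX_A4)]


@dataclass(frozen=True)
class SamplingSchedule:
    """Observation-time layout of the emulated study."""

    scan_offset_means: tuple[float, ...] = (4.6, 23.8, 163.2)
    scan_offset_sds: tuple[float, ...] = (0.95, 4.5, 11.0)
    psa_interval_weeks: float = 4.0
    baseline_psa_window_weeks: float = 6.0

    def __post_init__(self) -> None:
        if len(self.scan_offset_means) != len(self.scan_offset_sds):
            raise ValueError("offset means and sds must have equal length")
        if any(m <= 0 for m in self.scan_offset_means):
            raise ValueError("scan offsets must be positive")
        if any(m2 <= m1 for m1, m2 in zip(self.scan_offset_means,
                                          self.scan_offset_means[1:])):
            raise ValueError("scan offset means must be increasing")
        if self.baseline_psa_window_weeks >= 6.0001:
            raise ValueError("baseline PSA window must be < 6 weeks")


def blood_correction(value: float | np.ndarray, direction: str = "to_corrected"):
    """SPECT-blood concentration correction (MBq/L).

    ``to_corrected``: (raw − 6.27)/0.828 — the analysis-side correction,
    which can yield negative values at low raw concentrations.
    ``to_raw`` is the exact inverse.
    """
    v = np.asarray(value, dtype=float)
    if direction == "to_corrected":
        out = (v - BLOOD_CORRECTION_INTERCEPT) / BLOOD_CORRECTION_SLOPE
    elif direction == "to_raw":
        out = v * BLOOD_CORRECTION_SLOPE + BLOOD_CORRECTION_INTERCEPT
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float(out) if np.ndim(value) == 0 else out


def generate_spect_dataset(
    population: VirtualPopulation,
    regimen: Regimen,
    params: PKParameters | None = None,
    pd_params: PDParameters | None = None,
    variances: VarianceParameters | None = None,
    schedule: SamplingSchedule | None = None,
    seed: int | np.random.Generator = 0,
    apply_filters: bool = False,
    n_cycles_observed: int | None = None,
    rtol: float = 1e-8,
) -> ObservationSet:
    """SPECT observation rows (plus dose events) for every subject.

    Scan times are drawn per cycle from the schedule's offset distributions;
    true decay-corrected values come from each subject's own trajectory;
    residual error is applied per compartment.  Blood values are passed
    through ``blood_correction(to_raw)`` and back, emulating the measurement
    chain; with ``apply_filters`` rows whose corrected blood value is
    negative are dropped (the study's early-time-point exclusions).
    """
    params = params if params is not None else PKParameters()
    pd_params = pd_params if pd_params is not None else PDParameters()
    variances = variances if variances is not None else VarianceParameters()
    schedule = schedule if schedule is not None else SamplingSchedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigmas = residual_models(variances)
    n_cyc = n_cycles_observed if n_cycles_observed is not None else regimen.n_cycles

    rows = []
    for subject in population.subjects:
        ip = individualize_subject(params, pd_params, subject,
                                   max_cycles=max(regimen.n_cycles, 1))
        dose_times = regimen.dose_times
        scan_times: list[tuple[float, int]] = []
        for ci, td in enumerate(dose_times[:n_cyc], start=1):
            for mu, sd in zip(schedule.scan_offset_means, schedule.scan_offset_sds):
                off = -1.0
                while off <= 0:
                    off = rng.normal(mu, sd) if sd > 0 else mu
                scan_times.append((float(td) + off, ci))
        grid = np.unique([t for t, _ in scan_times])
        traj = solve_pkpd(regimen, ip, grid, rtol=rtol)
        lam = params.lambda_phys
        for t, cycle in scan_times:
            j = int(np.searchsorted(grid, t))
            for cmt, state_idx in _CMT_BY_STATE:
                phys = traj.states[j, state_idx]
                corr = decay_correct_amounts(
                    np.array([phys]), np.array([t]), dose_times, lam
                )[0]
                tag = {1: "central", 2: "salivary", 3: "kidneys", 4: "tumor"}[cmt]
                if cmt == 1:
                    corr /= ip.pk_for_cycle(1).V1
                noisy = float(
                    np.atleast_1d(
                        corr * (1.0 + (rng.normal(0.0, sigmas[tag].sigma_prop)
                                       if sigmas[tag].sigma_prop > 0 else 0.0))
                    )[0]
                )
                if cmt == 1:
                    if sigmas[tag].sigma_add > 0:
                        noisy += rng.normal(0.0, sigmas[tag].sigma_add)
                    # measurement chain: what the scanner reports, re-corrected
                    noisy = blood_correction(blood_correction(noisy, "to_raw"),
                                             "to_corrected")
                if apply_filters and cmt == 1 and noisy < 0:
                    continue
                rows.append({
                    "ID": subject.id, "TIME": t, "EVID": 0, "AMT": 0.0,
                    "CMT": cmt, "DV": noisy, "MDV": 0,
                    "WT": subject.covariates.WT, "TV": subject.covariates.TV,
                    "CYCLE": cycle, "OCC": cycle,
                })
        for ci, ev in enumerate(regimen.dose_events, start=1):
            rows.append({
                "ID": subject.id, "TIME": ev.time, "EVID": 1, "AMT": ev.activity,
                "CMT": 1, "DV": np.nan, "MDV": 1,
                "WT": subject.covariates.WT, "TV": subject.covariates.TV,
                "CYCLE": ci, "OCC": ci,
            })
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID", "CMT"],
                                        kind="stable").reset_index(drop=True)
    return ObservationSet(df)


def generate_psa_series(
    population: VirtualPopulation,
    regimen: Regimen,
    params: PKParameters | None = None,
    pd_params: PDParameters | None = None,
    variances: VarianceParameters | None = None,
    schedule: SamplingSchedule | None = None,
    seed: int | np.random.Generator = 0,
    truncate_at: float | None = None,
    rtol: float = 1e-8,
) -> ObservationSet:
    """PSA observation rows: one baseline draw plus periodic draws.

    Baseline falls inside the pre-treatment window (< 6 weeks before the
    first dose); subsequent draws occur every ``psa_interval_weeks`` through
    the regimen horizon, optionally truncated at a "new treatment" time.
    Proportional residual error is applied.
    """
    params = params if params is not None else PKParameters()
    pd_params = pd_params if pd_params is not None else PDParameters()
    variances = variances if variances is not None else VarianceParameters()
    schedule = schedule if schedule is not None else SamplingSchedule()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = variances.sigma_prop_psa
    horizon = regimen.horizon if truncate_at is None else min(regimen.horizon, truncate_at)

    rows = []
    for subject in population.subjects:
        ip = individualize_subject(params, pd_params, subject,
                                   max_cycles=max(regimen.n_cycles, 1))
        t_baseline = -float(rng.uniform(0.0, schedule.baseline_psa_window_weeks
                                        * HOURS_PER_WEEK))
        draw_times = np.arange(
            schedule.psa_interval_weeks * HOURS_PER_WEEK,
            horizon + 1e-9,
            schedule.psa_interval_weeks * HOURS_PER_WEEK,
        )
        times = np.concatenate([[t_baseline], draw_times])
        traj = solve_pkpd(regimen, ip, np.sort(times), rtol=rtol)
        for t in np.sort(times):
            true = traj.psa_at(t)
            noisy = true * (1.0 + (rng.normal(0.0, sigma) if sigma > 0 else 0.0))
            rows.append({
                "ID": subject.id, "TIME": t, "EVID": 0, "AMT": 0.0,
                "CMT": 6, "DV": noisy, "MDV": 0,
                "WT": subject.covariates.WT, "TV": subject.covariates.TV,
                "CYCLE": 0, "OCC": 0,
            })
        for ci, ev in enumerate(regimen.dose_events, start=1):
            rows.append({
                "ID": subject.id, "TIME": ev.time, "EVID": 1, "AMT": ev.activity,
                "CMT": 1, "DV": np.nan, "MDV": 1,
                "WT": subject.covariates.WT, "TV": subject.covariates.TV,
                "CYCLE": ci, "OCC": ci,
            })
    df = pd.DataFrame(rows).sort_values(["ID", "TIME", "EVID", "CMT"],
                                        kind="stable").reset_index(drop=True)
    return ObservationSet(df)
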
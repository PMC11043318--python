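"""Tumor time-integrated activity (AUC) and exposure–response analysis.

The exposure metric is the integral of the physical tumor activity
concentration over the first two treatment cycles, in MBq·h/mL — the
time-integrated activity concentration used in radioligand dosimetry.  A
linear regression of percent PSA change (at nadir or at the last
observation) on AUC is inverted to give the AUC required for a ≥ 50% PSA
decrease.

Reference thresholds estimated on the clinical cohort (709.5 MBq·h/mL for
the nadir endpoint, 1188 MBq·h/mL for the last-value endpoint) are exposed
as documented constants in :mod:`lupsma.params`; they derive from patient
data and are not recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulation import HOURS_PER_WEEK

DEFAULT_WINDOW_WEEKS = 12.0


@dataclass(frozen=True)
class ExposureRecord:
    """Per-subject exposure and PSA-change summary."""

    subject_id: int
    auc_tumor: float          # MBq·h/mL over the exposure window
    pct_change_nadir: float   # % change of nadir PSA vs baseline
    pct_change_last: float    # % change of last PSA vs baseline

    def __post_init__(self) -> None:
        if self.auc_tumor < 0:
            raise ValueError("AUC must be >= 0")
        if self.pct_change_nadir < -100 or self.pct_change_last < -100:
            raise ValueError("percent changes cannot fall below -100")


def tumor_auc(
    trajectory,
    tumor_volume: float | None = None,
    window: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal tumor AUC in MBq·h/mL over [t0, t_end].

    The trajectory must be in physical-decay mode (time-integrated activity
    is a physical quantity); the default window is the first twelve weeks,
    covering the first two cycles of either clinical regimen including
    wash-out before any third exposure.
    """
    if trajectory.decay_mode != "physical":
        raise ValueError("tumor AUC requires a physical-decay trajectory")
    tv = tumor_volume if tumor_volume is not None else trajectory.tumor_volume
    if tv <= 0:
        raise ValueError("tumor_volume must be > 0")
    t0, t_end = window if window is not None else (0.0, DEFAULT_WINDOW_WEEKS * HOURS_PER_WEEK)
    times = trajectory.times
    if t0 < times[0] - 1e-9 or t_end > times[-1] + 1e-9:
        raise ValueError(f"window [{t0}, {t_end}] h outside solved range")
    grid = np.union1d(times[(times >= t0) & (times <= t_end)], [t0, t_end])
    conc = np.interp(grid, times, trajectory.A4) / tv / 1000.0  # MBq/mL
    return float(np.trapezoid(conc, grid))


def psa_percent_changes(trajectory, baseline_psa: float,
                        window: tuple[float, float]) -> tuple[float, float]:
    """(% change at nadir, % change at last point) within a window."""
    t0, t_end = window
    mask = (trajectory.times >= t0) & (trajectory.times <= t_end)
    psa = trajectory.psa[mask]
    if not len(psa):
        raise ValueError("window contains no trajectory points")
    nadir = float(psa.min())
    last = float(psa[-1])
    return (100.0 * (nadir / baseline_psa - 1.0),
            100.0 * (last / baseline_psa - 1.0))


def fit_exposure_response(
    exposures: list[ExposureRecord] | pd.DataFrame,
    endpoint: str = "nadir",
):
    """OLS of percent PSA change on tumor AUC.

    Returns the fitted statsmodels results object; ``params`` holds the
    intercept and the AUC slope.
    """
    if endpoint not in ("nadir", "last"):
        raise ValueError("endpoint must be 'nadir' or 'last'")
    if isinstance(exposures, pd.DataFrame):
        df = exposures
    else:
        df = pd.DataFrame([
            {"auc_tumor": e.auc_tumor,
             "pct_change_nadir": e.pct_change_nadir,
             "pct_change_last": e.pct_change_last}
            for e in exposures
        ])
    if len(df) < 3 or df["auc_tumor"].nunique() < 2:
        raise ValueError("need >= 3 records with non-constant AUC")
    y = df[f"pct_change_{endpoint}"].to_numpy(dtype=float)
    X = sm.add_constant(df["auc_tumor"].to_numpy(dtype=float))
    return sm.OLS(y, X).fit()


def auc_threshold(slope: float, intercept: float, target_pct: float = -50.0) -> float:
    """AUC at which the fitted line reaches the target percent change."""
    if slope >= 0:
        raise ValueError("no attainable threshold: slope must be negative")
    return (target_pct - intercept) / slope
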
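"""Shared fixtures and an independent fixed-step RK4 oracle.

The oracle re-implements the model equations from scratch (its own
right-hand side, its own dosing/cycle bookkeeping) so that agreement with
the package's adaptive solver is a genuine two-route check.
"""

import math

import numpy as np
import pytest

from lupsma.params import (CovariateSet, PDParameters, PKParameters,
                           VarianceParameters)
from lupsma.simulation import build_regimen


@pytest.fixture
def typical_pk() -> PKParameters:
    return PKParameters()


@pytest.fixture
def typical_pd() -> PDParameters:
    return PDParameters()


@pytest.fixture
def variances() -> VarianceParameters:
    return VarianceParameters()


@pytest.fixture
def zero_variances() -> VarianceParameters:
    return VarianceParameters.zeroed()


@pytest.fixture
def median_cov() -> CovariateSet:
    return CovariateSet()


@pytest.fixture
def regimen_2x2():
    return build_regimen("2x2_repeated")


@pytest.fixture
def regimen_4x6():
    return build_regimen("4x6")


def rk4_oracle(
    doses,
    k14_fractions,
    t_end: float,
    h: float = 0.01,
    lam: float | None = None,
    out_times=(),
    with_pd: bool = False,
    bmax: float = 134.0,
    rates: dict | None = None,
):
    """Brute-force fixed-step RK4 integration of the full system.

    ``doses`` is a list of (time, activity); ``k14_fractions`` one fraction
    per dose.  Returns {t: state(7,)} at the requested output times.
    """
    r = {
        "k10": 0.253, "k12": 0.0105, "k21": 0.0629, "k13": 0.0321,
        "k31": 0.0625, "k14": 0.00967, "k41": 0.0150, "k15": 0.275,
        "k51": 0.0247,
    }
    if rates:
        r.update(rates)
    lam = math.log(2) / 159.528 if lam is None else lam
    TV = 0.0443
    kG, ke0 = 0.000408, 0.00128
    kDdir, kDdel = 0.00335 / 24 / 1000, 3.28e-5 / 24
    psa0 = 140.0 + 57.5

    def rhs(y, k14c, active):
        A1, A2, A3, A4, A5, Ce, PSA = y
        f12 = r["k12"] * A1 * (1 - A2 / bmax)
        d = np.empty(7)
        d[0] = (-(r["k10"] + r["k13"] + k14c + r["k15"] + lam) * A1 - f12
                + r["k21"] * A2 + r["k31"] * A3 + r["k41"] * A4 + r["k51"] * A5)
        d[1] = f12 - (r["k21"] + lam) * A2
        d[2] = r["k13"] * A1 - (r["k31"] + lam) * A3
        d[3] = k14c * A1 - (r["k41"] + lam) * A4
        d[4] = r["k15"] * A1 - (r["k51"] + lam) * A5
        if with_pd and active:
            C = max(A4, 0.0) / TV
            d[5] = ke0 * (C - Ce)
            d[6] = (kG - kDdir * C - kDdel * max(Ce, 0.0)) * PSA
        else:
            d[5] = 0.0
            d[6] = kG * PSA if with_pd else 0.0
        return d

    y = np.zeros(7)
    if with_pd:
        y[6] = psa0
    res = {}
    out_times = sorted(out_times)
    oi = di = 0
    k14c = r["k14"]
    active = False
    n = int(round(t_end / h))
    for step in range(n + 1):
        t = step * h
        while di < len(doses) and abs(t - doses[di][0]) < h / 2:
            y[0] += doses[di][1]
            k14c = r["k14"] * k14_fractions[di]
            active = active or doses[di][1] > 0
            di += 1
        while oi < len(out_times) and abs(t - out_times[oi]) < h / 2:
            res[out_times[oi]] = y.copy()
            oi += 1
        if step == n:
            break
        k1 = rhs(y, k14c, active)
        k2 = rhs(y + h / 2 * k1, k14c, active)
        k3 = rhs(y + h / 2 * k2, k14c, active)
        k4 = rhs(y + h * k3, k14c, active)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return res
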
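"""MAP objective/estimation and naive-pooled parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from lupsma.estimation import (ObservationSet, map_estimate, map_objective,
                               naive_pooled_fit, predict_observations)
from lupsma.params import (CovariateSet, PDParameters, PKParameters, Subject,
                           VarianceParameters)
from lupsma.simulation import VirtualPopulation, build_regimen
from lupsma.synthetic import SamplingSchedule, generate_spect_dataset

FIXED_SCHEDULE = SamplingSchedule(scan_offset_sds=(0.0, 0.0, 0.0))


def _noise_free_dataset(eta=None, n_subjects=1, n_cycles=2):
    subjects = [
        Subject(id=i + 1, covariates=CovariateSet(), eta=dict(eta or {}))
        for i in range(n_subjects)
    ]
    reg = build_regimen("2x2_repeated")
    ds = generate_spect_dataset(
        VirtualPopulation(subjects), reg,
        variances=VarianceParameters.zeroed(), schedule=FIXED_SCHEDULE,
        seed=1, n_cycles_observed=n_cycles,
    )
    return ds, reg


class TestObservationSet:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            ObservationSet(pd.DataFrame({"ID": [1]}))

    def test_unknown_cmt_rejected(self):
        ds, _ = _noise_free_dataset()
        bad = ds.data.copy()
        bad.loc[3, "CMT"] = 9
        with pytest.raises(ValueError, match="CMT"):
            ObservationSet(bad)

    def test_non_monotone_times_rejected(self):
        ds, _ = _noise_free_dataset()
        bad = ds.data.copy()
        bad.loc[0, "TIME"] = 1e9
        with pytest.raises(ValueError, match="non-monotone"):
            ObservationSet(bad)


class TestMapObjective:
    def test_zero_eta_minimizes_on_typical_data(self):
        ds, reg = _noise_free_dataset()
        obs = ds.observations(1)
        args = (obs, reg, CovariateSet(), PKParameters(), PDParameters(),
                VarianceParameters())
        at_truth = map_objective({"k14": 0.0, "k10": 0.0}, *args)
        for delta in ({"k14": 0.3, "k10": 0.0}, {"k14": 0.0, "k10": -0.3},
                      {"k14": 0.2, "k10": 0.2}):
            assert map_objective(delta, *args) > at_truth

    def test_single_observation_closed_form(self):
        """Proportional-error likelihood term checked against the hand formula."""
        ds, reg = _noise_free_dataset()
        obs = ds.observations(1)
        row = obs[obs["CMT"] == 4].iloc[[0]]
        variances = VarianceParameters()
        from lupsma.covariates import individualize

        ip = individualize(PKParameters(), PDParameters(), CovariateSet(),
                           max_cycles=4)
        pred = predict_observations(row, reg, ip)[0]
        got = map_objective({}, row, reg, CovariateSet(), PKParameters(),
                            PDParameters(), variances)
        var = (0.327 * pred) ** 2
        expected = math.log(2 * math.pi * var) + (row["DV"].iloc[0] - pred) ** 2 / var
        assert got == pytest.approx(expected, rel=1e-9)

    def test_prior_penalty_vanishes_for_large_omega(self):
        ds, reg = _noise_free_dataset()
        obs = ds.observations(1)
        huge = VarianceParameters().replace(omega_k14=1e6)
        base = map_objective({}, obs, reg, CovariateSet(), PKParameters(),
                             PDParameters(), huge)
        with_eta = map_objective({"k14": 0.5}, obs, reg, CovariateSet(),
                                 PKParameters(), PDParameters(), huge)
        # the difference is purely the likelihood; penalty is ~0.5²/1e12
        assert with_eta - base > 1.0
        penalty_only = (0.5 / 1e6) ** 2
        assert penalty_only < 1e-10

    def test_zero_omega_rejected(self):
        ds, reg = _noise_free_dataset()
        with pytest.raises(ValueError, match="omega"):
            map_objective({"k14": 0.1}, ds.observations(1), reg, CovariateSet(),
                          PKParameters(), PDParameters(),
                          VarianceParameters.zeroed())


class TestMapEstimate:
    def test_recovers_known_eta_from_noise_free_data(self):
        """With noise-free data and a tight residual model the MAP estimate
        converges to the generating random effects."""
        truth = {"k14": 0.4, "k13": -0.25}
        ds, reg = _noise_free_dataset(eta=truth)
        tight = VarianceParameters().replace(
            sigma_prop_central=0.001, sigma_add_central=0.001,
            sigma_prop_salivary=0.001, sigma_prop_kidneys=0.001,
            sigma_prop_tumor=0.001)
        res = map_estimate(ds.observations(1), reg, CovariateSet(),
                           PKParameters(), PDParameters(), tight,
                           eta_names=("k14", "k13"), n_starts=1, rtol=1e-8,
                           xtol=1e-8)
        assert res.eta["k14"] == pytest.approx(0.4, abs=1e-3)
        assert res.eta["k13"] == pytest.approx(-0.25, abs=1e-3)

    def test_objective_trace_monotone(self):
        ds, reg = _noise_free_dataset(eta={"k14": 0.3})
        res = map_estimate(ds.observations(1), reg, CovariateSet(),
                           PKParameters(), PDParameters(), VarianceParameters(),
                           eta_names=("k14",), n_starts=1, rtol=1e-6)
        assert all(b <= a for a, b in zip(res.trace, res.trace[1:]))

    def test_shrinkage_without_informative_data(self):
        """Without tumor observations the tumor-uptake η shrinks toward the
        prior mean despite the data being generated with a large effect."""
        ds, reg = _noise_free_dataset(eta={"k14": 0.8})
        no_tumor = ObservationSet(ds.data[ds.data["CMT"] != 4].reset_index(drop=True))
        res = map_estimate(no_tumor.observations(1), reg, CovariateSet(),
                           PKParameters(), PDParameters(), VarianceParameters(),
                           eta_names=("k14",), n_starts=1, rtol=1e-6)
        assert abs(res.eta["k14"]) < 0.4

    def test_requires_observations(self):
        _, reg = _noise_free_dataset()
        with pytest.raises(ValueError, match="observation"):
            map_estimate(pd.DataFrame(columns=["TIME", "CMT", "DV"]), reg,
                         CovariateSet(), PKParameters(), PDParameters(),
                         VarianceParameters())


class TestNaivePooledFit:
    def test_recovers_excretion_rate(self):
        ds, _ = _noise_free_dataset(n_subjects=3)
        res = naive_pooled_fit(ds, free=["k10"], start={"k10": 0.4})
        assert res.estimates["k10"] == pytest.approx(0.253, rel=0.01)

    def test_recovers_cycle2_fraction(self):
        ds, _ = _noise_free_dataset(n_subjects=3)
        tumor = ObservationSet(
            ds.data[(ds.data["EVID"] == 1) | (ds.data["CMT"] == 4)]
            .reset_index(drop=True))
        res = naive_pooled_fit(tumor, free=["cycle2"], start={"cycle2": 0.5})
        assert res.estimates["cycle2"] == pytest.approx(0.731, rel=0.01)

    def test_non_identifiable_parameter_flat_curvature(self, caplog):
        """Tumor-only data cannot inform the PSA growth rate."""
        ds, _ = _noise_free_dataset()
        tumor = ObservationSet(
            ds.data[(ds.data["EVID"] == 1) | (ds.data["CMT"] == 4)]
            .reset_index(drop=True))
        with caplog.at_level("WARNING"):
            res = naive_pooled_fit(tumor, free=["kG"], start={"kG": 0.001})
        assert ("not identifiable" in caplog.text
                or res.se.get("kG", 0.0) > 10 * res.estimates["kG"])

    def test_unknown_parameter_rejected(self):
        ds, _ = _noise_free_dataset()
        with pytest.raises(ValueError, match="unknown free parameter"):
            naive_pooled_fit(ds, free=["k99"])
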
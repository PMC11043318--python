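"""Study-like dataset emulation: blood correction, SPECT and PSA series."""

import numpy as np
import pytest

from lupsma.covariates import individualize_subject
from lupsma.estimation import predict_observations
from lupsma.params import (CovariateSet, PDParameters, PKParameters, Subject,
                           VarianceParameters)
from lupsma.simulation import VirtualPopulation, build_regimen, \
    generate_virtual_population
from lupsma.synthetic import (SamplingSchedule, blood_correction,
                              generate_psa_series, generate_spect_dataset)

FIXED = SamplingSchedule(scan_offset_sds=(0.0, 0.0, 0.0))


def _population(n):
    return VirtualPopulation(
        [Subject(id=i + 1, covariates=CovariateSet()) for i in range(n)])


class TestBloodCorrection:
    def test_intercept_cancellation(self):
        assert blood_correction(6.27) == pytest.approx(0.0)

    def test_round_trip_identity(self):
        for x in (-3.0, 0.0, 5.0, 123.4):
            assert blood_correction(blood_correction(x, "to_raw")) == pytest.approx(x)

    def test_low_raw_value_goes_negative(self):
        assert blood_correction(5.0) == pytest.approx(-1.534, abs=0.001)

    def test_unknown_direction(self):
        with pytest.raises(ValueError):
            blood_correction(1.0, "sideways")


class TestSpectDataset:
    def test_noise_free_dataset_matches_predictions(self):
        pop = _population(2)
        reg = build_regimen("2x2_repeated")
        ds = generate_spect_dataset(pop, reg,
                                    variances=VarianceParameters.zeroed(),
                                    schedule=FIXED, seed=1, n_cycles_observed=2)
        for subject in pop.subjects:
            obs = ds.observations(subject.id)
            ip = individualize_subject(PKParameters(), PDParameters(), subject,
                                       max_cycles=reg.n_cycles)
            preds = predict_observations(obs, reg, ip)
            assert np.allclose(obs["DV"].to_numpy(), preds, rtol=1e-9)

    def test_clinical_row_count(self):
        """76 subjects × 2 cycles × 3 scans × 4 compartments = 1824 rows."""
        pop = _population(76)
        ds = generate_spect_dataset(pop, build_regimen("2x2_repeated"),
                                    variances=VarianceParameters.zeroed(),
                                    schedule=FIXED, seed=2, n_cycles_observed=2)
        assert len(ds.observations()) == 1824

    def test_fixed_seed_reproducible(self, tmp_path):
        from lupsma.io import write_dataset

        pop = generate_virtual_population(4, seed=3)
        reg = build_regimen("4x6")
        paths = []
        for i in (0, 1):
            ds = generate_spect_dataset(pop, reg, seed=9, n_cycles_observed=2)
            p = tmp_path / f"ds{i}.csv"
            write_dataset(ds, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_filters_only_remove_rows(self):
        pop = _population(10)
        reg = build_regimen("2x2_repeated")
        kwargs = dict(variances=VarianceParameters(), schedule=FIXED, seed=5,
                      n_cycles_observed=2)
        raw = generate_spect_dataset(pop, reg, apply_filters=False, **kwargs)
        filt = generate_spect_dataset(pop, reg, apply_filters=True, **kwargs)
        raw_obs = raw.observations()
        filt_obs = filt.observations()
        assert len(filt_obs) <= len(raw_obs)
        # negative corrected blood values are what got dropped
        dropped = len(raw_obs) - len(filt_obs)
        negatives = ((raw_obs["CMT"] == 1) & (raw_obs["DV"] < 0)).sum()
        assert dropped == negatives
        # surviving values are untouched
        merged = filt_obs.merge(raw_obs, on=["ID", "TIME", "CMT"], how="left",
                                suffixes=("_f", "_r"))
        assert np.allclose(merged["DV_f"], merged["DV_r"])

    def test_scan_time_jitter_matches_schedule(self):
        pop = _population(150)
        sched = SamplingSchedule()
        ds = generate_spect_dataset(pop, build_regimen("2x2_repeated"),
                                    variances=VarianceParameters.zeroed(),
                                    schedule=sched, seed=6, n_cycles_observed=2)
        obs = ds.observations()
        dose_t = {1: 0.0, 2: 336.0}
        offsets = obs["TIME"] - obs["CYCLE"].map(dose_t)
        first = offsets[(offsets < 10)]
        assert first.mean() == pytest.approx(4.6, abs=0.2)
        assert first.std() == pytest.approx(0.95, rel=0.2)


class TestPsaSeries:
    def test_noise_free_on_trajectory(self):
        pop = _population(2)
        reg = build_regimen("4x6")
        ds = generate_psa_series(pop, reg, variances=VarianceParameters.zeroed(),
                                 seed=7)
        for subject in pop.subjects:
            obs = ds.observations(subject.id)
            ip = individualize_subject(PKParameters(), PDParameters(), subject,
                                       max_cycles=reg.n_cycles)
            preds = predict_observations(obs, reg, ip)
            assert np.allclose(obs["DV"].to_numpy(), preds, rtol=1e-7)

    def test_untreated_series_strictly_increasing(self):
        pop = _population(1)
        reg = build_regimen("2x2_repeated")
        ds = generate_psa_series(pop, reg, pd_params=PDParameters(kD_direct=0.0,
                                                                 kD_delay=0.0),
                                 variances=VarianceParameters.zeroed(), seed=8)
        dv = ds.observations(1)["DV"].to_numpy()
        assert np.all(np.diff(dv) > 0)

    def test_row_count_with_monthly_draws(self):
        """Baseline + 6 four-weekly draws over 24 weeks → 7 per subject."""
        pop = _population(76)
        ds = generate_psa_series(pop, build_regimen("2x2_repeated"),
                                 variances=VarianceParameters.zeroed(), seed=9)
        obs = ds.observations()
        assert len(obs) == 76 * 7 == 532
        assert (obs.groupby("ID").size() == 7).all()

    def test_baseline_inside_pretreatment_window(self):
        pop = _population(5)
        ds = generate_psa_series(pop, build_regimen("4x6"),
                                 variances=VarianceParameters.zeroed(), seed=10)
        baselines = ds.observations().groupby("ID")["TIME"].min()
        assert (baselines < 0).all()
        assert (baselines >= -6 * 168.0).all()

    def test_schedule_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            SamplingSchedule(scan_offset_means=(24.0, 5.0, 160.0))
        with pytest.raises(ValueError, match="positive"):
            SamplingSchedule(scan_offset_means=(-1.0, 5.0, 160.0))
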
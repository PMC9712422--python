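"""Anthropometric-interaction volume regression: fits, splits, metrics."""

import numpy as np
import pandas as pd
import pytest

from eitlung.errors import (
    CollinearityError,
    ContractError,
    DegenerateFitError,
    EITLungValidationError,
    UndefinedMetricError,
    UnfittedModelError,
)
from eitlung.phantom import C1, C2, C3, KAPPA0, Subject, generate_cohort
from eitlung.volumize import (
    Dataset,
    VolumeModel,
    fit_per_subject,
    fit_volume_model,
    metrics,
    predict_volume,
    split_train_test,
)
from eitlung.waveform import ConductivityCurve, VolumeCurve


def law_slope(subject, lung_area=1.0):
    """The generator's volume-per-conductivity slope for one subject."""
    return (C1 + C2 * subject.w_h + C3 * subject.chest) / (KAPPA0 * lung_area)


def make_dataset(cohort, n_samples=20, noise_sd=0.0, seed=0, lung_area=1.0):
    """Samples following the built-in slope law exactly (plus volume noise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in cohort:
        dsig = rng.uniform(0, 0.2, n_samples)
        vol = law_slope(s, lung_area) * dsig
        if noise_sd > 0:
            vol = vol + rng.normal(0, noise_sd, n_samples)
        for k in range(n_samples):
            rows.append((s.id, dsig[k], vol[k], k, "full-fast"))
    return Dataset.from_samples(rows)


class TestFitPerSubject:
    def test_exact_line(self):
        rows = [("s1", x, 2 * x + 1, i, "p") for i, x in enumerate([0.0, 0.5, 1.0, 2.0])]
        slope, intercept, pcc = fit_per_subject(Dataset.from_samples(rows))
        assert slope == pytest.approx(2.0, rel=1e-12)
        assert intercept == pytest.approx(1.0, rel=1e-12)
        assert pcc == pytest.approx(1.0, abs=1e-12)

    def test_recovers_generator_slope(self):
        subj = generate_cohort(1, seed=9)[0]
        ds = make_dataset([subj])
        slope, intercept, _ = fit_per_subject(ds)
        assert slope == pytest.approx(law_slope(subj), rel=1e-6)
        assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_slope_correlates_with_w_h_across_cohort(self):
        """The slope law makes slope vs W/H strongly correlated."""
        from scipy.stats import pearsonr

        cohort = generate_cohort(30, seed=2)
        slopes = [fit_per_subject(make_dataset([s], seed=i))[0] for i, s in enumerate(cohort)]
        wh = [s.w_h for s in cohort]
        assert pearsonr(slopes, wh)[0] > 0.9

    def test_zero_variance_rejected(self):
        rows = [("s1", 0.5, v, i, "p") for i, v in enumerate([1.0, 2.0, 3.0])]
        with pytest.raises(DegenerateFitError):
            fit_per_subject(Dataset.from_samples(rows))


class TestSplit:
    @pytest.fixture()
    def dataset(self):
        return make_dataset(generate_cohort(14, seed=1), n_samples=20)

    def test_study_size_split_fraction(self, dataset):
        """14 subjects x 20 samples, 2 held out + 10%: 64/280 ~ 22.9%."""
        train, test = split_train_test(dataset, seed=0)
        assert len(test) == 2 * 20 + 24 == 64  # ceil(0.10 * 12 * 20) = 24
        assert len(train) + len(test) == 280
        assert len(test) / 280 == pytest.approx(0.2286, abs=1e-3)

    def test_partition(self, dataset):
        train, test = split_train_test(dataset, seed=3)
        key = ["subject_id", "trial", "paradigm", "dsig"]
        tr = set(map(tuple, train.df[key].itertuples(index=False)))
        te = set(map(tuple, test.df[key].itertuples(index=False)))
        assert not tr & te
        assert len(tr) + len(te) == len(dataset)

    def test_seeded_determinism(self, dataset):
        a = split_train_test(dataset, seed=7)
        b = split_train_test(dataset, seed=7)
        pd.testing.assert_frame_equal(a[0].df, b[0].df)
        pd.testing.assert_frame_equal(a[1].df, b[1].df)

    def test_too_few_subjects(self):
        ds = make_dataset(generate_cohort(3, seed=0))
        with pytest.raises(EITLungValidationError):
            split_train_test(ds)


class TestFitVolumeModel:
    def test_exact_recovery_noise_free(self):
        """Noise-free generator data lies in the basis span: coefficients and
        held-out predictions recovered to 1e-6 relative."""
        cohort = generate_cohort(10, seed=4)
        ds = make_dataset(cohort, lung_area=0.5)
        train, test = split_train_test(ds, seed=1)
        model = fit_volume_model(train, cohort)
        coef = dict(zip(model.basis, model.coefficients))
        assert coef["dsig"] == pytest.approx(C1 / (KAPPA0 * 0.5), rel=1e-6)
        assert coef["dsig_wh"] == pytest.approx(C2 / (KAPPA0 * 0.5), rel=1e-6)
        assert coef["dsig_chest"] == pytest.approx(C3 / (KAPPA0 * 0.5), rel=1e-6)
        for name in ("const", "wh", "chest"):
            assert abs(coef[name]) < 1e-6
        by_id = {s.id: s for s in cohort}
        for sid in test.subjects():
            sub_df = test.restrict(sid).df
            pred = model.predict_samples(sub_df["dsig"].to_numpy(), by_id[sid])
            np.testing.assert_allclose(pred, sub_df["volume_L"], rtol=1e-6, atol=1e-9)

    def test_holding_out_subjects_does_not_degrade_recovery(self):
        """Generalization across anthropometrics: fit without two subjects,
        predict them exactly (noise-free)."""
        cohort = generate_cohort(8, seed=5)
        train = make_dataset(cohort[:6])
        model = fit_volume_model(train, cohort)
        for s in cohort[6:]:
            dsig = np.linspace(0.01, 0.2, 7)
            pred = model.predict_samples(dsig, s)
            np.testing.assert_allclose(pred, law_slope(s) * dsig, rtol=1e-6)

    def test_noisy_heldout_nrmse_under_5_percent(self):
        cohort = generate_cohort(50, seed=6)
        ds = make_dataset(cohort, n_samples=20, noise_sd=0.04, seed=6)
        train, test = split_train_test(ds, seed=2)
        model = fit_volume_model(train, cohort)
        by_id = {s.id: s for s in cohort}
        pred = np.concatenate(
            [
                model.predict_samples(test.restrict(sid).df["dsig"].to_numpy(), by_id[sid])
                for sid in test.subjects()
            ]
        )
        meas = np.concatenate(
            [test.restrict(sid).df["volume_L"].to_numpy() for sid in test.subjects()]
        )
        rmse = np.sqrt(np.mean((pred - meas) ** 2))
        nrmse = 100 * rmse / (meas.max() - meas.min())
        assert nrmse < 5.0

    def test_zero_dsig_collinearity_error(self):
        cohort = generate_cohort(4, seed=7)
        rows = [(s.id, 0.0, 1.0, k, "p") for s in cohort for k in range(5)]
        with pytest.raises(CollinearityError, match="dsig"):
            fit_volume_model(Dataset.from_samples(rows), cohort)

    def test_weight_is_never_a_regressor(self):
        cohort = generate_cohort(6, seed=8)
        model = fit_volume_model(make_dataset(cohort), cohort)
        assert "weight" not in model.basis
        assert set(model.basis) == {"const", "dsig", "dsig_wh", "dsig_chest", "wh", "chest"}

    def test_summary_and_json_roundtrip(self, tmp_path):
        cohort = generate_cohort(6, seed=9)
        model = fit_volume_model(make_dataset(cohort), cohort)
        assert "dsig_wh" in model.summary()
        p = tmp_path / "model.json"
        model.to_json(p)
        loaded = VolumeModel.from_json(p)
        np.testing.assert_allclose(loaded.coefficients, model.coefficients)


class TestPredictAndMetrics:
    @pytest.fixture()
    def fitted(self):
        cohort = generate_cohort(6, seed=10)
        return fit_volume_model(make_dataset(cohort), cohort), cohort[0]

    def test_zero_curve_gives_intercept_terms(self, fitted):
        model, subj = fitted
        t = np.arange(10) / 10.0
        curve = ConductivityCurve(t, np.zeros(10), 10.0)
        out = predict_volume(model, curve, subj)
        coef = dict(zip(model.basis, model.coefficients))
        expect = coef["const"] + coef["wh"] * subj.w_h + coef["chest"] * subj.chest
        np.testing.assert_allclose(out.volume, expect, atol=1e-9)

    def test_prediction_affine_in_dsig(self, fitted):
        model, subj = fitted
        t = np.arange(10) / 10.0
        base = predict_volume(model, ConductivityCurve(t, np.zeros(10), 10.0), subj).volume
        one = predict_volume(model, ConductivityCurve(t, np.ones(10), 10.0), subj).volume
        two = predict_volume(model, ConductivityCurve(t, np.full(10, 2.0), 10.0), subj).volume
        np.testing.assert_allclose(two - one, one - base, rtol=1e-9)

    def test_unfitted_model_rejected(self, fitted):
        _, subj = fitted
        t = np.arange(10) / 10.0
        with pytest.raises(UnfittedModelError):
            predict_volume(VolumeModel(), ConductivityCurve(t, np.zeros(10), 10.0), subj)

    def test_metrics_closed_forms(self):
        t = np.arange(100) / 10.0
        meas = VolumeCurve(t, 4 * np.abs(np.sin(0.3 * t)))
        ident = VolumeCurve(t, meas.volume.copy())
        pcc, nrmse = metrics(ident, meas)
        assert pcc == pytest.approx(1.0) and nrmse == pytest.approx(0.0, abs=1e-12)
        # constant 0.1 L offset on a 4 L range: NRMSE = 2.5%
        meas4 = VolumeCurve(t, 4 * (t - t.min()) / (t.max() - t.min()))
        off = VolumeCurve(t, meas4.volume + 0.1)
        pcc, nrmse = metrics(off, meas4)
        assert nrmse == pytest.approx(2.5, rel=1e-9)
        neg = VolumeCurve(t, -meas4.volume)
        assert metrics(neg, meas4)[0] == pytest.approx(-1.0)

    def test_nrmse_scale_invariance(self):
        t = np.arange(100) / 10.0
        meas = VolumeCurve(t, np.sin(t) + 2)
        pred = VolumeCurve(t, np.sin(t) + 2.2)
        _, n1 = metrics(pred, meas)
        _, n2 = metrics(VolumeCurve(t, 3 * pred.volume), VolumeCurve(t, 3 * meas.volume))
        assert n1 == pytest.approx(n2, rel=1e-12)

    def test_zero_range_rejected(self):
        t = np.arange(10) / 10.0
        with pytest.raises(UndefinedMetricError):
            metrics(VolumeCurve(t, np.ones(10)), VolumeCurve(t, np.ones(10)))

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ContractError):
            metrics(
                VolumeCurve(np.arange(10) / 10.0, np.arange(10.0)),
                VolumeCurve(np.arange(10) / 5.0, np.arange(10.0)),
            )
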
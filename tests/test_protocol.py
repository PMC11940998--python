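import numpy as np
import pytest

import sersclass as sc
from sersclass.metrics import FoldMetrics, ROCResult
from sersclass.protocol import FoldResult

from conftest import SMALL_AXIS

TINY_AXIS = sc.WavenumberAxis(517.0, 1913.0, 120)


def cohort(classes, seed=0, axis=TINY_AXIS):
    return sc.generate_cohort(sc.SyntheticConfig(axis=axis, classes=classes, seed=seed))


class TestBalanceClasses:
    def test_large_imbalance_reduces_to_minority_patient_count(self):
        ds = cohort((("resp", 41, 3), ("chf", 103, 3)), seed=1)
        bal = sc.balance_classes(ds, sc.ProtocolConfig(seed=2))
        assert len(bal.patients_of_class("resp")) == 41
        assert len(bal.patients_of_class("chf")) == 41

    def test_equal_groups_draw_three_spectra_each(self):
        ds = cohort((("copd", 11, 4), ("ba", 11, 4)), seed=3)
        bal = sc.balance_classes(ds, sc.ProtocolConfig(spectra_per_patient_draw=3, seed=4))
        for lab in ("copd", "ba"):
            n = sum(1 for s in bal.spectra if s.class_label == lab)
            assert n == 33

    def test_already_balanced_patients_unchanged_with_large_draw(self):
        ds = cohort((("a", 5, 2), ("b", 5, 2)), seed=5)
        cfg = sc.ProtocolConfig(spectra_per_patient_draw=2, seed=6)
        bal = sc.balance_classes(ds, cfg)
        assert set(bal.class_of_patient) == set(ds.class_of_patient)
        assert bal.n_spectra == ds.n_spectra

    def test_patients_short_on_replicates_are_resampled_with_replacement(self):
        ds = cohort((("a", 3, 2), ("b", 3, 2)), seed=7)
        bal = sc.balance_classes(ds, sc.ProtocolConfig(spectra_per_patient_draw=5, seed=8))
        assert all(len(bal.spectra_of_patient(p)) == 5 for p in bal.class_of_patient)

    def test_single_class_dataset_rejected(self):
        ds = cohort((("only", 4, 2),), seed=9)
        with pytest.raises(ValueError, match="2 classes"):
            sc.balance_classes(ds, sc.ProtocolConfig())


class TestPatientSplit:
    def test_train_and_test_patients_disjoint(self, rng):
        ds = cohort((("a", 10, 3), ("b", 10, 3)), seed=10)
        for _ in range(10):
            train, test = sc.patient_split(ds, 0.8, rng)
            assert not set(train.class_of_patient) & set(test.class_of_patient)
            assert set(train.class_of_patient) | set(test.class_of_patient) == set(ds.class_of_patient)

    def test_spectra_count_near_target_fraction(self, rng):
        # 22 patients x 3 spectra at fraction 0.8: nearest feasible whole-patient
        # train sizes around 52.8 are 51 and 54
        ds = cohort((("a", 11, 3), ("b", 11, 3)), seed=11)
        for _ in range(10):
            train, _ = sc.patient_split(ds, 0.8, rng)
            assert train.n_spectra in (51, 54)

    def test_even_halves_with_two_patients_per_class(self, rng):
        ds = cohort((("a", 2, 3), ("b", 2, 3)), seed=12)
        train, test = sc.patient_split(ds, 0.5, rng)
        for part in (train, test):
            assert len(part.patients_of_class("a")) == 1
            assert len(part.patients_of_class("b")) == 1

    def test_both_classes_required_on_both_sides(self, rng):
        ds = cohort((("a", 1, 3), ("b", 5, 3)), seed=13)
        with pytest.raises(ValueError, match="2 patients per class"):
            sc.patient_split(ds, 0.8, rng)


class TestRunProtocol:
    @pytest.mark.parametrize("P,T", [(1, 1), (2, 3)])
    def test_fold_count_is_p_times_t(self, P, T):
        ds = cohort((("a", 6, 3), ("b", 8, 3)), seed=14)
        results = sc.run_protocol(
            ds, sc.PreprocessConfig(), sc.PLSConfig(K=4, max_lv=4),
            sc.ProtocolConfig(P=P, T=T, seed=15),
        )
        assert len(results) == P * T
        assert [r.fold_id for r in results] == [(p + 1, t + 1) for p in range(P) for t in range(T)]

    def test_no_patient_leakage_in_any_fold(self):
        ds = cohort((("a", 6, 3), ("b", 8, 3)), seed=16)
        results = sc.run_protocol(
            ds, sc.PreprocessConfig(), sc.PLSConfig(K=4, max_lv=4),
            sc.ProtocolConfig(P=3, T=2, seed=17),
        )
        for r in results:
            assert not r.train_patient_ids & r.test_patient_ids
            assert r.n_lv_used >= 1

    def test_seed_reproducibility(self):
        ds = cohort((("a", 6, 3), ("b", 8, 3)), seed=18)
        args = (sc.PreprocessConfig(), sc.PLSConfig(K=4, max_lv=4))
        r1 = sc.run_protocol(ds, *args, sc.ProtocolConfig(P=2, T=2, seed=19))
        r2 = sc.run_protocol(ds, *args, sc.ProtocolConfig(P=2, T=2, seed=19))
        for a, b in zip(r1, r2):
            assert a.n_lv_used == b.n_lv_used
            assert a.test_metrics == b.test_metrics
            assert np.array_equal(a.vip, b.vip)
        r3 = sc.run_protocol(ds, *args, sc.ProtocolConfig(P=2, T=2, seed=20))
        assert any(not np.array_equal(a.vip, c.vip) for a, c in zip(r1, r3))


def _dummy_fold(fold_id, test_acc, vip):
    m = FoldMetrics(tp=1, fp=0, tn=1, fn=0, sensitivity=1.0, specificity=1.0, accuracy=test_acc)
    roc = ROCResult(thresholds=np.array([np.inf, 1.0]), tpr=np.array([0.0, 1.0]),
                    fpr=np.array([0.0, 1.0]), auc=test_acc)
    return FoldResult(
        fold_id=fold_id, n_lv_used=1, train_metrics=m, test_metrics=m,
        train_roc=roc, test_roc=roc, vip=np.asarray(vip, dtype=float),
        train_patient_ids=frozenset({"p1"}), test_patient_ids=frozenset({"p2"}),
    )


class TestAggregate:
    def test_mean_min_max_arithmetic(self):
        folds = [_dummy_fold((1, i + 1), acc, [1.0, 1.0]) for i, acc in enumerate([0.8, 0.9, 1.0])]
        summary = sc.aggregate(folds)
        assert summary.stats["test"]["accuracy"] == (pytest.approx(0.9), 0.8, 1.0)
        assert summary.n_folds == 3

    def test_single_fold_collapses_statistics(self):
        summary = sc.aggregate([_dummy_fold((1, 1), 0.75, [2.0, 0.5])])
        for metrics in summary.stats.values():
            for mean, mn, mx in metrics.values():
                assert mean == mn == mx

    def test_matches_bruteforce_reduction_on_real_run(self):
        ds = cohort((("a", 6, 3), ("b", 8, 3)), seed=21)
        results = sc.run_protocol(
            ds, sc.PreprocessConfig(), sc.PLSConfig(K=4, max_lv=4),
            sc.ProtocolConfig(P=2, T=2, seed=22),
        )
        summary = sc.aggregate(results)
        accs = [r.test_metrics.accuracy for r in results]
        assert summary.stats["test"]["accuracy"] == (
            pytest.approx(sum(accs) / len(accs)), min(accs), max(accs)
        )
        aucs = [r.train_roc.auc for r in results]
        assert summary.stats["train"]["roc_auc"] == (
            pytest.approx(sum(aucs) / len(aucs)), min(aucs), max(aucs)
        )
        assert np.allclose(summary.mean_vip, np.mean([r.vip for r in results], axis=0))

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="no fold"):
            sc.aggregate([])

    def test_min_le_mean_le_max_everywhere(self):
        folds = [_dummy_fold((1, i + 1), acc, [1.0]) for i, acc in enumerate([0.3, 0.6, 0.9, 1.0])]
        summary = sc.aggregate(folds)
        for metrics in summary.stats.values():
            for mean, mn, mx in metrics.values():
                assert mn <= mean <= mx


class TestVIPBandReport:
    def _summary(self, vip):
        return sc.ProtocolSummary(
            stats={}, mean_vip=np.asarray(vip, dtype=float), n_folds=1,
            positive_label="a", wavenumbers=SMALL_AXIS.grid(),
        )

    def test_flat_vip_gives_equal_values(self):
        summary = self._summary(np.ones(SMALL_AXIS.n_points))
        report = sc.vip_band_report(summary, sc.default_peak_library(), window_cm1=10.0)
        assert (report["mean_vip"] == 1.0).all()
        assert (report["rank"] == 1).all()

    def test_zero_window_is_exact_grid_lookup(self):
        grid = SMALL_AXIS.grid()
        vip = np.arange(len(grid), dtype=float)
        summary = self._summary(vip)
        report = sc.vip_band_report(summary, sc.default_peak_library(), window_cm1=0.0)
        for _, row in report.iterrows():
            nearest = int(np.argmin(np.abs(grid - row["band_cm1"])))
            assert row["mean_vip"] == vip[nearest]

    def test_peak_band_outranks_quiet_band(self):
        grid = SMALL_AXIS.grid()
        vip = np.ones(len(grid))
        vip[np.abs(grid - 638.0) < 12] = 4.0
        report = sc.vip_band_report(self._summary(vip), sc.default_peak_library(), window_cm1=10.0)
        assert report.iloc[0]["band_cm1"] == 638.0
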
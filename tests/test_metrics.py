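import numpy as np
import pytest

from emgsleep import (
    EXCLUDED,
    SLEEP,
    WAKE,
    BinaryHypnogram,
    PostureTrack,
    agreement,
    f_measure,
    mean_sd,
    posture_stratified,
    sleep_efficiency_compare,
    state_amplitude_histogram,
)
from emgsleep.formats import Channel, Recording

from naive import naive_agreement


def hypnos_from_counts(tp, tn, fp, fn):
    pred = [SLEEP] * tp + [WAKE] * tn + [SLEEP] * fp + [WAKE] * fn
    ref = [SLEEP] * tp + [WAKE] * tn + [WAKE] * fp + [SLEEP] * fn
    return BinaryHypnogram(pred), BinaryHypnogram(ref)


class TestAgreement:
    def test_hand_computed_confusion(self):
        pred, ref = hypnos_from_counts(tp=90, tn=5, fp=3, fn=2)
        s = agreement(pred, ref)
        assert (s.tp, s.tn, s.fp, s.fn) == (90, 5, 3, 2)
        assert s.sensitivity == pytest.approx(90 / 92, abs=1e-12)
        assert s.specificity == pytest.approx(5 / 8, abs=1e-12)
        assert s.accuracy == pytest.approx(0.95, abs=1e-12)
        # chance agreement from marginal products
        assert s.kappa == pytest.approx((0.95 - 0.8612) / (1 - 0.8612), abs=1e-9)

    def test_perfect_agreement(self):
        pred, ref = hypnos_from_counts(tp=10, tn=4, fp=0, fn=0)
        s = agreement(pred, ref)
        for v in (s.sensitivity, s.specificity, s.ppv, s.npv, s.accuracy, s.kappa, s.f_measure):
            assert v == pytest.approx(1.0)

    def test_matches_naive_loop_on_random_pairs(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(2, 1000))
            labels = np.array([SLEEP, WAKE, EXCLUDED], dtype=object)
            pred = BinaryHypnogram(list(labels[rng.integers(0, 3, n)]))
            ref = BinaryHypnogram(list(labels[rng.integers(0, 3, n)]))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ours = agreement(pred, ref).as_dict()
            naive = naive_agreement(pred.states, ref.states)
            for k, v in naive.items():
                if isinstance(v, float) and np.isnan(v):
                    assert np.isnan(ours[k]), k
                else:
                    assert ours[k] == pytest.approx(v, abs=1e-12), k

    def test_kappa_against_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(37)
        for _ in range(20):
            n = int(rng.integers(10, 500))
            pred = [(SLEEP, WAKE)[i] for i in rng.integers(0, 2, n)]
            ref = [(SLEEP, WAKE)[i] for i in rng.integers(0, 2, n)]
            if len(set(ref)) < 2 or len(set(pred)) < 2:
                continue
            ours = agreement(BinaryHypnogram(pred), BinaryHypnogram(ref)).kappa
            theirs = sklearn_metrics.cohen_kappa_score(pred, ref)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_excluded_dropped_pairwise(self):
        pred = BinaryHypnogram([SLEEP, EXCLUDED, WAKE, SLEEP])
        ref = BinaryHypnogram([SLEEP, SLEEP, WAKE, EXCLUDED])
        s = agreement(pred, ref)
        assert s.n_epochs == 2
        assert s.accuracy == 1.0

    def test_single_class_reference_warns(self):
        pred = BinaryHypnogram([SLEEP, WAKE])
        ref = BinaryHypnogram([SLEEP, SLEEP])
        with pytest.warns(UserWarning, match="single class"):
            s = agreement(pred, ref)
        assert np.isnan(s.kappa)
        assert np.isnan(s.specificity)
        assert s.tp + s.tn + s.fp + s.fn == 2

    def test_kappa_invariant_under_label_swap(self):
        rng = np.random.default_rng(41)
        swap = {SLEEP: WAKE, WAKE: SLEEP}
        for _ in range(20):
            n = int(rng.integers(10, 200))
            pred = [(SLEEP, WAKE)[i] for i in rng.integers(0, 2, n)]
            ref = [(SLEEP, WAKE)[i] for i in rng.integers(0, 2, n)]
            if len(set(ref)) < 2 or len(set(pred)) < 2:
                continue
            k1 = agreement(BinaryHypnogram(pred), BinaryHypnogram(ref)).kappa
            k2 = agreement(
                BinaryHypnogram([swap[s] for s in pred]),
                BinaryHypnogram([swap[s] for s in ref]),
            ).kappa
            assert k1 == pytest.approx(k2, abs=1e-12)

    def test_positive_class_switch(self):
        pred, ref = hypnos_from_counts(tp=90, tn=5, fp=3, fn=2)
        s = agreement(pred, ref, positive=WAKE)
        assert (s.tp, s.tn) == (5, 90)
        assert s.sensitivity == pytest.approx(5 / 8)

    def test_f_variants(self):
        assert f_measure(0.56, 0.99) == pytest.approx(0.7153, abs=5e-4)
        pred, ref = hypnos_from_counts(tp=90, tn=5, fp=3, fn=2)
        s_pr = agreement(pred, ref, f_variant="ppv_sens")
        s_ss = agreement(pred, ref, f_variant="sens_spec")
        assert s_pr.f_measure == pytest.approx(
            2 * s_pr.ppv * s_pr.sensitivity / (s_pr.ppv + s_pr.sensitivity)
        )
        assert s_ss.f_measure == pytest.approx(
            2 * s_ss.sensitivity * s_ss.specificity / (s_ss.sensitivity + s_ss.specificity)
        )


class TestSleepEfficiency:
    @pytest.mark.parametrize(
        "se_ref,se_est,abs_d,rel_d",
        [
            (94.1, 96.6, 2.5, 2.7),   # largest published discrepancy
            (98.2, 97.5, 0.7, 0.7),
            (97.0, 97.0, 0.0, 0.0),
        ],
    )
    def test_reference_denominated_relative_difference(self, se_ref, se_est, abs_d, rel_d):
        c = sleep_efficiency_compare(se_ref, se_est)
        assert c.abs_diff == pytest.approx(abs_d, abs=1e-9)
        assert round(c.rel_diff, 1) == rel_d

    def test_from_hypnograms(self):
        ref = BinaryHypnogram([SLEEP] * 9 + [WAKE])
        est = BinaryHypnogram([SLEEP] * 8 + [WAKE] * 2)
        c = sleep_efficiency_compare(ref, est)
        assert c.se_ref == pytest.approx(90.0)
        assert c.se_est == pytest.approx(80.0)
        assert c.rel_diff == pytest.approx(100 * 10 / 90)

    def test_zero_reference_undefined(self):
        c = sleep_efficiency_compare(0.0, 50.0)
        assert np.isnan(c.rel_diff)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sleep_efficiency_compare(101.0, 50.0)


class TestPostureStratified:
    def test_single_posture_equals_global(self):
        pred, ref = hypnos_from_counts(tp=50, tn=5, fp=2, fn=3)
        track = PostureTrack(["SUPINE"] * len(pred))
        strata = posture_stratified(pred, ref, track)
        assert strata["SUPINE"].n_epochs == 60
        assert strata["SUPINE"].kappa == pytest.approx(agreement(pred, ref).kappa)

    def test_absent_posture_reported_empty(self):
        pred, ref = hypnos_from_counts(tp=5, tn=5, fp=0, fn=0)
        track = PostureTrack(["SUPINE"] * len(pred))
        strata = posture_stratified(pred, ref, track)
        assert strata["PRONE"].n_epochs == 0
        assert np.isnan(strata["PRONE"].kappa)

    def test_per_stratum_matches_subset_computation(self):
        rng = np.random.default_rng(53)
        n = 400
        pred = BinaryHypnogram([(SLEEP, WAKE)[i] for i in rng.integers(0, 2, n)])
        ref = BinaryHypnogram([(SLEEP, WAKE)[i] for i in rng.integers(0, 2, n)])
        track = PostureTrack(
            [("SUPINE", "LEFT")[i] for i in rng.integers(0, 2, n)]
        )
        strata = posture_stratified(pred, ref, track)
        for posture in ("SUPINE", "LEFT"):
            idx = [i for i, p in enumerate(track.postures) if p == posture]
            sub = agreement(
                BinaryHypnogram([pred.states[i] for i in idx]),
                BinaryHypnogram([ref.states[i] for i in idx]),
            )
            assert strata[posture].kappa == pytest.approx(sub.kappa, abs=1e-12)
            assert strata[posture].n_epochs == len(idx)


class TestStateAmplitudeHistogram:
    def _recording(self, sleep_scale, wake_scale, n_epochs=40, fs=20, seed=0):
        rng = np.random.default_rng(seed)
        states = [SLEEP, WAKE] * (n_epochs // 2)
        spe = fs * 30
        x = np.concatenate(
            [
                rng.standard_normal(spe) * (sleep_scale if s == SLEEP else wake_scale)
                for s in states
            ]
        )
        return Recording([Channel("a", x)], fs), BinaryHypnogram(states)

    def test_histograms_are_unit_mass_on_unit_support(self):
        rec, ref = self._recording(1.0, 3.0)
        res = state_amplitude_histogram(rec, ref, bins=40)
        assert res.bin_edges[0] == 0.0 and res.bin_edges[-1] == 1.0
        for h in res.histograms.values():
            assert h.sum() == pytest.approx(1.0)

    def test_wake_amplitudes_detected(self):
        """A 3x wake amplitude scale separates the states (p < 0.05)."""
        rec, ref = self._recording(1.0, 3.0, seed=1)
        res = state_amplitude_histogram(rec, ref)
        assert res.p_value < 0.05
        assert res.epoch_means[WAKE].mean() > res.epoch_means[SLEEP].mean()

    def test_single_state_skips_test(self):
        rng = np.random.default_rng(2)
        rec = Recording([Channel("a", rng.standard_normal(20 * 30 * 2))], 20)
        ref = BinaryHypnogram([SLEEP, SLEEP])
        with pytest.warns(UserWarning, match="one state"):
            res = state_amplitude_histogram(rec, ref)
        assert np.isnan(res.p_value)
        assert set(res.histograms) == {SLEEP}

    def test_constant_signal_single_bin(self):
        rec = Recording([Channel("a", np.ones(20 * 60))], 20)
        ref = BinaryHypnogram([SLEEP, WAKE])
        res = state_amplitude_histogram(rec, ref, bins=10)
        for h in res.histograms.values():
            assert h[-1] == pytest.approx(1.0)  # all mass at normalized 1.0


class TestMeanSd:
    def test_sample_sd(self):
        m, sd = mean_sd([1.0, 2.0, 3.0])
        assert m == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_nan_aware(self):
        m, sd = mean_sd([1.0, np.nan, 3.0])
        assert m == pytest.approx(2.0)
        assert sd == pytest.approx(np.sqrt(2.0))
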
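import numpy as np
import pytest

from distexp import (
    ShrinkageLDA,
    SimConfig,
    cross_class_decode,
    decode_timecourse,
    generate_design,
    multiclass_auc,
    prepare_decoding_epochs,
    simulate_epochs,
    time_resolved_cv_decode,
    window_average_auc,
)
from distexp.data_model import DecodingResult
from distexp.exceptions import InsufficientDataError, LeakageError, ParameterError
from distexp.synth import class_topographies

from conftest import make_epochs, make_trials


class TestPrepare:
    def test_resamples_512_to_128(self, montage):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.normal(0, 1, (2, 68, 1024)), montage,
                         sfreq=512.0, tmin_ms=-1000.0, trials=make_trials(2))
        out = prepare_decoding_epochs(ep, baseline=(-1000.0, -800.0))
        assert out.sfreq == 128.0
        assert out.data.shape[-1] == 1024 // 4

    def test_constant_trial_zero_after_baseline(self, montage):
        ep = make_epochs(np.full((1, 68, 1024), 2.5), montage, sfreq=512.0,
                         tmin_ms=-1000.0, trials=make_trials(1))
        out = prepare_decoding_epochs(ep, baseline=(-1000.0, -800.0))
        assert np.abs(out.data).max() < 1e-9

    def test_sine_amplitude_preserved(self, montage):
        sfreq, n = 512.0, 2048
        t = np.arange(n) / sfreq
        data = np.tile(np.sin(2 * np.pi * 5.0 * t), (1, 68, 1))
        ep = make_epochs(data, montage, sfreq=sfreq, tmin_ms=0.0,
                         trials=make_trials(1))
        out = prepare_decoding_epochs(ep, baseline=(0.0, 4000.0 / 512 * 100))
        mid = slice(out.data.shape[-1] // 4, 3 * out.data.shape[-1] // 4)
        amp = np.abs(out.data[0, 0, mid]).max()
        assert abs(amp - 1.0) < 0.02


class TestShrinkageLDA:
    def test_two_class_1d_boundary_at_zero(self):
        """Closed-form LDA: symmetric means +-1 put the boundary at 0."""
        X = np.array([[-1.5], [-0.5], [0.5], [1.5]])
        y = np.array(["a", "a", "b", "b"])
        clf = ShrinkageLDA(shrinkage=0.0).fit(X, y)
        s = clf.decision_function(np.array([[0.0]]))
        assert np.isclose(s[0, 0], s[0, 1])
        assert clf.predict(np.array([[-2.0], [2.0]])).tolist() == ["a", "b"]

    def test_full_shrinkage_is_diagonal_classifier(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 5))
        y = rng.choice(["a", "b"], 40)
        clf = ShrinkageLDA(shrinkage=1.0).fit(X, y)
        # manual diagonal-covariance discriminant
        means = np.stack([X[y == c].mean(0) for c in clf.classes_])
        Xc = X - means[(y == clf.classes_[1]).astype(int)]
        S = (Xc.T @ Xc) / (len(X) - 2)
        coef = (means / np.diag(S)).astype(float)
        assert np.allclose(clf.coef_, coef)

    def test_sklearn_estimator_protocol(self):
        clf = ShrinkageLDA(shrinkage=0.5)
        assert clf.get_params() == {"shrinkage": 0.5}
        clf.set_params(shrinkage="auto")
        assert clf.shrinkage == "auto"

    def test_auto_shrinkage_in_unit_interval(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (30, 20))
        y = rng.choice(["a", "b", "c"], 30)
        clf = ShrinkageLDA().fit(X, y)
        assert 0.0 <= clf.shrinkage_ <= 1.0


class TestMulticlassAUC:
    def test_perfect_and_chance(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        scores = np.zeros((10, 2))
        scores[:, 0] = -np.arange(10.0)  # class a scores highest for a-trials
        scores[:, 1] = np.arange(10.0)
        assert multiclass_auc(scores, y) == 1.0
        rng = np.random.default_rng(0)
        y2 = rng.choice(["a", "b", "c"], 3000)
        s2 = rng.normal(0, 1, (3000, 3))
        assert abs(multiclass_auc(s2, y2) - 0.5) < 0.02

    def test_rank_formula_equals_pair_enumeration(self):
        """Mann-Whitney ranks == brute-force pair counting, ties = 0.5."""
        rng = np.random.default_rng(7)
        y = rng.choice(["a", "b", "c"], 30)
        scores = rng.integers(0, 5, (30, 3)).astype(float)  # forces ties
        classes = np.array(["a", "b", "c"])
        brute = []
        for j, cls in enumerate(classes):
            pos = scores[y == cls, j]
            neg = scores[y != cls, j]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            brute.append(wins / (len(pos) * len(neg)))
        assert np.isclose(multiclass_auc(scores, y, classes), np.mean(brute))

    def test_absent_class_skipped_with_warning(self):
        y = np.array(["a", "a", "b", "b"])
        scores = np.array([[1., 0, 0], [2, 0, 0], [0, 1, 0], [0, 2, 0]])
        with pytest.warns(UserWarning, match="absent"):
            auc = multiclass_auc(scores, y, classes=np.array(["a", "b", "c"]))
        assert auc == 1.0


class TestDecodeTimecourse:
    def test_shuffled_labels_near_chance_and_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (90, 16, 6))
        y = np.repeat(["a", "b", "c"], 30)
        rng.shuffle(y)
        auc1, pf1 = decode_timecourse(X, y, k=10, seed=5)
        auc2, pf2 = decode_timecourse(X, y, k=10, seed=5)
        assert np.array_equal(auc1, auc2) and np.array_equal(pf1, pf2)
        assert abs(auc1.mean() - 0.5) < 0.06

    def test_auc_monotone_in_pattern_amplitude(self):
        """Stronger injected class patterns cannot decode worse."""
        rng = np.random.default_rng(1)
        v = {c: rng.normal(0, 1, 16) for c in "abc"}
        y = np.repeat(["a", "b", "c"], 40)
        noise = rng.normal(0, 1, (120, 16, 4))
        aucs = []
        for amp in (0.0, 0.4, 2.0):
            X = noise + amp * np.stack([v[c] for c in y])[:, :, None]
            auc, _ = decode_timecourse(X, y, k=10, seed=2)
            aucs.append(auc.mean())
        assert aucs[0] < aucs[1] < aucs[2]
        assert aucs[2] > 0.95

    def test_class_below_k_rejected(self):
        X = np.zeros((12, 4, 2))
        y = np.array(["a"] * 6 + ["b"] * 6)
        with pytest.raises(InsufficientDataError):
            decode_timecourse(X, y, k=10, seed=0)


@pytest.fixture(scope="module")
def decoding_sim(montage):
    """High-SNR Experiment-2 simulation with evoked + anticipatory patterns."""
    cfg = SimConfig(seed=41, experiment=2, blocks_per_condition=3,
                    n_sessions=1, sfreq=128, noise_white_sd=0.2,
                    noise_pink_sd=0.2, alpha_base_amp=0.0,
                    pattern_amp_evoked=4.0, pattern_amp_anticipatory=2.0)
    table = generate_design(cfg, 0)
    ep, _ = simulate_epochs(table, cfg, montage)
    return prepare_decoding_epochs(ep).crop(-600.0, 500.0)


class TestConditionDecoding:
    def test_injected_patterns_decoded_post_onset(self, decoding_sim):
        res = time_resolved_cv_decode(decoding_sim, "target_sf", k=10, seed=0)
        post = window_average_auc(res, (100.0, 400.0))
        assert all(v > 0.85 for v in post.values())

    def test_anticipatory_distractor_code_specific_to_dptv(self, decoding_sim):
        res = time_resolved_cv_decode(decoding_sim, "distractor_sf", k=10,
                                      seed=0)
        pre = window_average_auc(res, (-500.0, -250.0))
        assert pre["DpTv_unique"] > 0.9
        assert abs(pre["DpTp_identical"] - 0.5) < 0.1

    def test_deterministic(self, decoding_sim):
        r1 = time_resolved_cv_decode(decoding_sim, "target_sf", k=10, seed=3)
        r2 = time_resolved_cv_decode(decoding_sim, "target_sf", k=10, seed=3)
        assert np.array_equal(r1.auc, r2.auc)


class TestCrossClassDecoding:
    def test_overlapping_trials_raise(self, decoding_sim):
        with pytest.raises(LeakageError):
            cross_class_decode(decoding_sim, "distractor_sf", decoding_sim)

    def test_dissociation_and_below_chance(self, decoding_sim):
        """Independent role codes do not generalize; anti-associated blocked
        codes generalize below chance."""
        present = decoding_sim.trials["distractor_loc"].notna().to_numpy()
        train = decoding_sim.select_trials(present)
        test = decoding_sim.select_trials(~present)  # target-only trials
        res = cross_class_decode(train, "distractor_sf", test, "target_sf",
                                 seed=0)
        pre = window_average_auc(res, (-500.0, -250.0))
        ci = dict(zip(res.conditions, range(len(res.conditions))))
        # distractor and target codes are independent random topographies:
        # the anticipatory distractor code in DpTv says nothing about the
        # target's frequency
        assert abs(pre["DpTv_unique"] - 0.5) < 0.07
        # in DpTp_unique the blocked target frequency is anti-associated
        # with the trained distractor labels -> below-chance generalization
        assert pre["DpTp_unique"] < 0.35

    def test_shared_code_generalizes(self):
        """If train and test carry the same class patterns, cross-class AUC
        matches within-class performance."""
        rng = np.random.default_rng(4)
        v = {c: rng.normal(0, 1, 16) for c in "abc"}
        y_tr = np.repeat(["a", "b", "c"], 30)
        y_te = np.repeat(["a", "b", "c"], 15)
        Xtr = rng.normal(0, 0.5, (90, 16)) + np.stack([v[c] for c in y_tr])
        Xte = rng.normal(0, 0.5, (45, 16)) + np.stack([v[c] for c in y_te])
        Xanti = rng.normal(0, 0.5, (45, 16)) - np.stack([v[c] for c in y_te])
        clf = ShrinkageLDA().fit(Xtr, y_tr)
        auc_same = multiclass_auc(clf.decision_function(Xte), y_te,
                                  clf.classes_)
        auc_anti = multiclass_auc(clf.decision_function(Xanti), y_te,
                                  clf.classes_)
        assert auc_same > 0.9
        assert auc_anti < 0.1


class TestWindowAverage:
    def test_window_mean_is_arithmetic_mean(self):
        times = np.arange(-200.0, 600.0, 100.0)
        auc = np.vstack([np.full(len(times), 0.6),
                         np.full(len(times), 0.5)])
        res = DecodingResult(auc=auc, times=times,
                             conditions=("c1", "c2"), train_class="target",
                             test_class="target")
        out = window_average_auc(res, (0.0, 500.0))
        assert out == {"c1": 0.6, "c2": 0.5}
        sel = (times >= 0) & (times <= 500)
        assert np.isclose(out["c1"], auc[0, sel].mean())

    def test_empty_window_rejected(self):
        res = DecodingResult(auc=np.full((1, 3), 0.5),
                             times=np.array([0.0, 10.0, 20.0]),
                             conditions=("c",), train_class="target",
                             test_class="target")
        with pytest.raises(ParameterError):
            window_average_auc(res, (100.0, 200.0))
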
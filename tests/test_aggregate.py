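"""Quantile-signature aggregation, patient-level calibrated SVM, and
task cut points."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemil import synthetic_cohort as sc
from hemil.aggregate import (
    CutPoints,
    PatientModel,
    TrainedPipeline,
    UnscorablePatientError,
    classify,
    fit_patient_model,
    predict_core,
    predict_patient,
    quantile_signature,
    select_cut_point,
)
from hemil.instance_model import fit_instance_ensemble, predict_instance_prob


def brute_force_quantiles(values, levels):
    """Independent inverse-CDF oracle: explicit linear interpolation of
    the sorted sample at positions level * (n - 1)."""
    srt = np.sort(np.asarray(values, dtype=float))
    n = len(srt)
    out = []
    for q in levels:
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        out.append(srt[lo] + (pos - lo) * (srt[hi] - srt[lo]))
    return np.array(out)


class TestQuantileSignature:
    def test_constant_input(self):
        sig = quantile_signature([0.5] * 7)
        assert np.allclose(sig.values, 0.5)

    def test_two_point_input_interpolates_linearly(self):
        sig = quantile_signature([0.0, 1.0])
        assert np.allclose(sig.values, np.arange(16) / 15)

    def test_order_statistics_properties(self, rng):
        probs = rng.random(37)
        sig = quantile_signature(probs)
        assert np.all(np.diff(sig.values) >= 0)
        assert np.isclose(sig.values[0], probs.min())
        assert np.isclose(sig.values[-1], probs.max())

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_interpolation(self, probs):
        sig = quantile_signature(probs)
        oracle = brute_force_quantiles(probs, np.linspace(0, 1, 16))
        assert np.allclose(sig.values, oracle, atol=1e-12)

    def test_permutation_and_duplication_invariance(self, rng):
        probs = rng.random(20)
        a = quantile_signature(probs).values
        b = quantile_signature(rng.permutation(probs)).values
        assert np.allclose(a, b)
        # interpolated quantiles are exactly distribution-determined only
        # in the large-sample limit; duplication shifts interpolation
        # knots by O(1/n)
        c = quantile_signature(np.concatenate([probs, probs])).values
        assert np.allclose(a, c, atol=0.05)
        big = rng.random(2000)
        d = quantile_signature(big).values
        e = quantile_signature(np.concatenate([big, big])).values
        assert np.allclose(d, e, atol=2e-3)

    def test_midpoint_level_convention(self):
        sig = quantile_signature([0.0, 1.0], midpoint_levels=True)
        assert np.allclose(sig.levels, (np.arange(16) + 0.5) / 16)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            quantile_signature([])


class TestClassify:
    @pytest.mark.parametrize(
        "task,prob,expected",
        [
            ("grade", 0.80, 0), ("grade", 0.801, 1),
            ("er", 0.50, 0), ("er", 0.51, 1),
            ("basal", 0.60, 0), ("basal", 0.61, 1),
            ("ror", 0.20, 0), ("ror", 0.21, 1),
            ("histology", 0.10, 0), ("histology", 0.11, 1),
        ],
    )
    def test_strict_cut_points(self, task, prob, expected):
        """Calls flip only strictly above each task's cut point (0.80
        grade, 0.50 ER, 0.60 Basal, 0.20 ROR, 0.10 lobular)."""
        assert classify(prob, task) == expected

    def test_monotone_in_probability(self):
        for task in sc.TASKS:
            calls = [classify(p, task) for p in np.linspace(0, 1, 101)]
            assert np.all(np.diff(calls) >= 0)

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError, match="task"):
            classify(0.5, "stage")


@pytest.fixture(scope="module")
def er_pipeline(small_config, small_cohort):
    train = [r for r in small_cohort if r.split == "train"]
    bags = [sc.synthesize_feature_bag(r, "er", small_config) for r in train]
    labels = [r.binary_label("er") for r in train]
    ensemble = fit_instance_ensemble(bags, labels, seed=1, task="er")
    sigs = [quantile_signature(predict_instance_prob(ensemble, b)) for b in bags]
    model = fit_patient_model(sigs, labels, seed=1)
    return TrainedPipeline(task="er", ensemble=ensemble, patient_model=model)


class TestPatientModel:
    def test_separable_cohort_high_heldout_accuracy(self, er_pipeline, small_config, small_cohort):
        test = [r for r in small_cohort if r.split == "test"]
        correct = 0
        for r in test:
            bag = sc.synthesize_feature_bag(r, "er", small_config)
            call = classify(predict_patient(er_pipeline, bag), "er")
            correct += call == r.binary_label("er")
        assert correct / len(test) >= 0.90

    def test_shuffled_labels_fall_to_majority_rate(self, small_config, small_cohort):
        train = [r for r in small_cohort if r.split == "train"]
        bags = [sc.synthesize_feature_bag(r, "er", small_config) for r in train]
        labels = np.array([r.binary_label("er") for r in train])
        rng = np.random.default_rng(5)
        test = [r for r in small_cohort if r.split == "test"]
        truth = np.array([r.binary_label("er") for r in test])
        majority = max(truth.mean(), 1 - truth.mean())
        accs = []
        for _ in range(4):
            shuffled = rng.permutation(labels)
            ens = fit_instance_ensemble(bags, shuffled, seed=1, task="er")
            sigs = [quantile_signature(predict_instance_prob(ens, b)) for b in bags]
            model = fit_patient_model(sigs, shuffled, seed=1)
            pipe = TrainedPipeline(task="er", ensemble=ens, patient_model=model)
            calls = [
                classify(predict_patient(pipe, sc.synthesize_feature_bag(r, "er", small_config)), "er")
                for r in test
            ]
            accs.append(np.mean(np.array(calls) == truth))
        se = np.sqrt(majority * (1 - majority) / (len(test) * 4))
        assert np.mean(accs) <= majority + 4 * se

    def test_duplicated_training_set_same_decision(self, small_config, small_cohort):
        train = [r for r in small_cohort if r.split == "train"]
        bags = [sc.synthesize_feature_bag(r, "er", small_config) for r in train]
        labels = [r.binary_label("er") for r in train]
        ens = fit_instance_ensemble(bags, labels, seed=1, task="er")
        sigs = [quantile_signature(predict_instance_prob(ens, b)) for b in bags]
        m1 = fit_patient_model(sigs, labels, seed=1)
        m2 = fit_patient_model(sigs + sigs, labels + labels, seed=1)
        x = np.stack([s.values for s in sigs])
        assert np.allclose(m1.decision(x), m2.decision(x), atol=1e-4)

    def test_single_class_rejected(self):
        sigs = [quantile_signature([0.2, 0.4]) for _ in range(6)]
        with pytest.raises(ValueError, match="single class"):
            fit_patient_model(sigs, [1] * 6)

    def test_sigmoid_map_monotone(self, er_pipeline):
        model = er_pipeline.patient_model
        s = np.linspace(-20, 20, 1000)
        p = 1 / (1 + np.exp(-(model.sigmoid_a * s + model.sigmoid_b)))
        assert np.all(np.diff(p) >= -1e-15)


class TestPredict:
    def test_identical_cores_match_single_core(self, er_pipeline, small_config, small_cohort):
        r = next(x for x in small_cohort if x.n_cores >= 2)
        bag = sc.synthesize_feature_bag(r, "er", small_config)
        one_core = bag.vectors[bag.core_ids == 0]
        dup = sc.FeatureBag(
            patient_id=r.patient_id,
            core_ids=np.repeat([0, 1], len(one_core)),
            offsets=np.zeros((2 * len(one_core), 2), int),
            vectors=np.concatenate([one_core, one_core]),
        )
        single = sc.FeatureBag(
            patient_id=r.patient_id,
            core_ids=np.zeros(len(one_core), int),
            offsets=np.zeros((len(one_core), 2), int),
            vectors=one_core,
        )
        assert np.isclose(predict_patient(er_pipeline, dup), predict_patient(er_pipeline, single))

    def test_mixed_cores_bracketed_by_extremes(self, er_pipeline, small_config, small_cohort):
        """A patient with three strongly-positive cores and one negative
        core scores between the per-core extremes."""
        pos = next(r for r in small_cohort if r.er == "positive")
        neg = next(r for r in small_cohort if r.er == "negative")
        bag_p = sc.synthesize_feature_bag(pos, "er", small_config)
        bag_n = sc.synthesize_feature_bag(neg, "er", small_config)
        k = small_config.regions_per_core
        d = bag_p.dim
        mixed = sc.FeatureBag(
            patient_id="mix",
            core_ids=np.repeat([0, 1, 2, 3], k),
            offsets=np.zeros((4 * k, 2), int),
            vectors=np.concatenate(
                [np.resize(bag_p.vectors, (3 * k, d)), np.resize(bag_n.vectors, (k, d))]
            ),
        )
        p_mixed = predict_patient(er_pipeline, mixed)
        per_core = [predict_core(er_pipeline, mixed, c) for c in range(4)]
        assert min(per_core) - 1e-9 <= p_mixed <= max(per_core) + 1e-9
        # heterogeneous cores disagree while the patient gets one call
        assert max(per_core) - min(per_core) > 0.2

    def test_core_order_invariance(self, er_pipeline, small_config, small_cohort):
        r = next(x for x in small_cohort if x.n_cores >= 2)
        bag = sc.synthesize_feature_bag(r, "er", small_config)
        perm = np.random.default_rng(3).permutation(len(bag))
        shuffled = sc.FeatureBag(
            patient_id=r.patient_id, core_ids=bag.core_ids[perm],
            offsets=bag.offsets[perm], vectors=bag.vectors[perm],
        )
        assert np.isclose(
            predict_patient(er_pipeline, bag), predict_patient(er_pipeline, shuffled)
        )

    def test_single_region_core_constant_signature(self, er_pipeline, small_config, small_cohort):
        bag = sc.synthesize_feature_bag(small_cohort[0], "er", small_config)
        single = sc.FeatureBag(
            patient_id="s", core_ids=np.zeros(1, int),
            offsets=np.zeros((1, 2), int), vectors=bag.vectors[:1],
        )
        p_region = predict_instance_prob(er_pipeline.ensemble, single)[0]
        sig = quantile_signature([p_region])
        expected = er_pipeline.patient_model.predict_proba(sig.values)[0]
        assert np.isclose(predict_core(er_pipeline, single, 0), expected)

    def test_unscorable_patient_raises(self, er_pipeline):
        empty = sc.FeatureBag(
            patient_id="e", core_ids=np.zeros(0, int),
            offsets=np.zeros((0, 2), int),
            vectors=np.zeros((0, er_pipeline.ensemble.dim)),
        )
        with pytest.raises(UnscorablePatientError):
            predict_patient(er_pipeline, empty)


class TestSelectCutPoint:
    def test_separated_clusters_cut_in_gap(self):
        probs = [0.08, 0.1, 0.12, 0.88, 0.9, 0.92]
        truths = [0, 0, 0, 1, 1, 1]
        cut = select_cut_point(probs, truths)
        assert 0.12 < cut < 0.88

    def test_lowest_candidate_on_ties(self):
        # cuts 0.3 and 0.7 both reach J = 0.5; the rule picks the lowest
        probs = [0.2, 0.4, 0.6, 0.8]
        truths = [0, 1, 0, 1]
        assert select_cut_point(probs, truths) == pytest.approx(0.3)

    def test_no_signal_still_deterministic(self, rng):
        probs = rng.random(50)
        truths = rng.integers(0, 2, 50)
        while len(np.unique(truths)) < 2:
            truths = rng.integers(0, 2, 50)
        a = select_cut_point(probs, truths)
        b = select_cut_point(probs, truths)
        assert a == b

    def test_bimodal_histogram_cut_between_modes(self, rng):
        """A grade-style bimodal probability histogram yields a cut in
        the valley, matching a brute-force Youden scan."""
        lo = rng.beta(2, 8, 200)  # low-intermediate mode near 0.2
        hi = rng.beta(8, 2, 100)  # high-grade mode near 0.8
        probs = np.concatenate([lo, hi])
        truths = np.concatenate([np.zeros(200, int), np.ones(100, int)])
        cut = select_cut_point(probs, truths)
        # brute-force Youden oracle over every threshold
        uniq = np.unique(probs)
        cands = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2, [1.0]))
        js = [
            ((probs > c) & (truths == 1)).sum() / 100
            + (~(probs > c) & (truths == 0)).sum() / 200
            - 1
            for c in cands
        ]
        assert np.isclose(
            max(js),
            ((probs > cut) & (truths == 1)).sum() / 100
            + (~(probs > cut) & (truths == 0)).sum() / 200
            - 1,
        )
        assert 0.2 < cut < 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            select_cut_point([0.1, 0.9], [1, 1])
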
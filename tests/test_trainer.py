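"""Transfer-task orchestration: chronological splitting, AUC evaluation,
baseline isolation, determinism and learnability on easy tasks."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from msalign import (
    DomainDataset,
    SimConfig,
    TrainConfig,
    TransferTask,
    Trial,
    chronological_label_split,
    evaluate_auc,
    generate_transfer_pair,
    run_experiment,
    run_repeated_experiment,
    train_baseline,
    train_msa,
)
from msalign.models import EEGNet, EEGNetConfig, MSAModel
from msalign.trainer import MSA_METHOD, MethodConfig, prepare_task
from tests.conftest import make_dataset


def labeled_dataset(rng, n_per_class=10, n_subjects=1):
    """Alternating-label trials with increasing start times per subject."""
    trials = []
    for s in range(n_subjects):
        for i in range(2 * n_per_class):
            sig = rng.standard_normal((2, 16)).astype(np.float32)
            trials.append(Trial(sig, i % 2, f"s{s}", "d", float(i)))
    return DomainDataset(trials, 2, 128.0)


class TestChronologicalSplit:
    def test_counts_at_20_percent(self, rng):
        ds = labeled_dataset(rng, n_per_class=10)
        labeled, test = chronological_label_split(ds, 20)
        assert len(labeled) == 4 and len(test) == 16  # 2 + 2 labeled
        by_class = {0: 0, 1: 0}
        for t in labeled:
            by_class[t.label] += 1
        assert by_class == {0: 2, 1: 2}

    @pytest.mark.parametrize("frac", [5, 10, 15, 20])
    def test_standard_fractions_accepted(self, rng, frac):
        ds = labeled_dataset(rng, n_per_class=20)
        labeled, test = chronological_label_split(ds, frac)
        assert len(labeled) + len(test) == len(ds)

    def test_partition_is_disjoint_and_exhaustive(self, rng):
        ds = make_dataset(rng, n_subjects=3, n_trials=11)
        labeled, test = chronological_label_split(ds, 15)
        ids = lambda pool: {id(t) for t in pool}
        assert ids(labeled) & ids(test) == set()
        assert len(labeled) + len(test) == len(ds)

    def test_no_test_clip_precedes_labeled_clip_same_class(self, rng):
        ds = make_dataset(rng, n_subjects=3, n_trials=13)
        labeled, test = chronological_label_split(ds, 20)
        for t in test:
            same = [l for l in labeled
                    if l.subject_id == t.subject_id and l.label == t.label]
            assert all(l.start_time <= t.start_time for l in same)

    def test_subject_missing_a_class_warns(self, rng):
        trials = [Trial(rng.standard_normal((2, 16)).astype(np.float32),
                        0, "s0", "d", float(i)) for i in range(5)]
        ds = DomainDataset(trials, 2, 128.0)
        with pytest.warns(UserWarning, match="class"):
            labeled, test = chronological_label_split(ds, 20)
        assert len(labeled) + len(test) == 5

    def test_invalid_fraction_rejected(self, rng):
        ds = labeled_dataset(rng)
        for bad in (0, 100, -5):
            with pytest.raises(ValueError):
                chronological_label_split(ds, bad)


class TestEvaluateAuc:
    @staticmethod
    def scored_model(scores_by_key):
        """A stub model whose seizure probability is looked up per trial."""
        class Stub:
            def predict_proba(self, X, project=False):
                return np.array([scores_by_key[x.tobytes()] for x in X])
        return Stub()

    def make_trials(self, rng, labels, scores):
        trials, table = [], {}
        for i, (lab, sc) in enumerate(zip(labels, scores)):
            sig = rng.standard_normal((2, 8)).astype(np.float32)
            trials.append(Trial(sig, lab, "s0", "d", float(i)))
            table[sig.tobytes()] = sc
        return trials, table

    def test_perfect_ordering_gives_one(self, rng):
        trials, table = self.make_trials(rng, [0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert evaluate_auc(self.scored_model(table), trials) == {"s0": 1.0}

    def test_all_tied_scores_give_half(self, rng):
        trials, table = self.make_trials(rng, [0, 1, 0, 1], [0.5] * 4)
        assert evaluate_auc(self.scored_model(table), trials) == {"s0": 0.5}

    def test_matches_bruteforce_pair_counting_with_ties(self, rng):
        labels = [0, 0, 0, 1, 1, 1]
        scores = [0.2, 0.5, 0.4, 0.5, 0.9, 0.7]  # one cross-class tie
        trials, table = self.make_trials(rng, labels, scores)
        got = evaluate_auc(self.scored_model(table), trials)["s0"]
        wins = ties = 0
        for sp, lp in zip(scores, labels):
            for sn, ln in zip(scores, labels):
                if lp == 1 and ln == 0:
                    wins += sp > sn
                    ties += sp == sn
        expected = (wins + 0.5 * ties) / (3 * 3)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_class_subject_skipped(self, rng):
        trials, table = self.make_trials(rng, [1, 1, 1], [0.1, 0.2, 0.3])
        assert evaluate_auc(self.scored_model(table), trials) == {}


def easy_task(seed=3, scenario="unsupervised", l=0):
    """A benign two-domain task: strong rhythm contrast, no artifacts."""
    cfg = SimConfig(
        n_latent=3, source_channels=8, target_channels=4,
        source_rate=128.0, target_rate=128.0, clip_seconds=1.0,
        n_subjects=2, clips_per_subject=60, seizure_fraction=0.5,
        seizure_gain=3.0, background_level_sigma=0.0,
        seizure_level_sigma=0.0, artifact_prob=0.0, sensor_snr=20.0,
        scenario=scenario, label_fraction=l, seed=seed,
    )
    return generate_transfer_pair(cfg)


def variance_oracle_auc(task):
    """Logistic regression on log clip variance, trained on source, scored
    per target subject — the independent learnability reference."""
    Xs = np.array([[np.log(t.signal.var())] for t in task.source.trials])
    clf = LogisticRegression().fit(Xs, task.source.labels)
    aucs = []
    for sid in task.target.subjects:
        trials = task.target.subject_trials(sid)
        y = [t.label for t in trials]
        p = clf.predict_proba(
            np.array([[np.log(t.signal.var())] for t in trials]))[:, 1]
        aucs.append(roc_auc_score(y, p))
    return float(np.mean(aucs))


class TestTraining:
    TC = TrainConfig(epochs=8, batch_size=16, seed=0, repeats=1)

    def test_loss_descends_on_separable_task(self):
        task = prepare_task(easy_task(), use_ea=True)
        model, _, history = train_msa(task, train_cfg=self.TC)
        assert history["total"][-1] < history["total"][0]

    def test_learnable_task_reaches_oracle_level(self):
        # the variance-threshold oracle certifies the task is easy; the
        # trained model must match it
        raw = easy_task(scenario="semi_supervised", l=20)
        assert variance_oracle_auc(raw) >= 0.95
        aucs, _ = run_experiment(raw, MSA_METHOD, train_cfg=self.TC)
        assert np.mean(list(aucs.values())) >= 0.95

    def test_within_baseline_learns_from_target_labels(self):
        raw = easy_task(scenario="semi_supervised", l=20)
        task = prepare_task(raw, use_ea=False)
        # the l% pool is tiny (24 clips), so the epoch budget is raised to
        # give a comparable number of gradient steps
        tc = TrainConfig(epochs=80, batch_size=16, seed=0, repeats=1)
        model, test_pool, _ = train_baseline(task, "within", train_cfg=tc)
        aucs = evaluate_auc(model, test_pool)
        assert np.mean(list(aucs.values())) >= 0.9

    def test_source_only_ignores_target_labels(self):
        raw = easy_task()
        task = prepare_task(raw, use_ea=False)
        m1, _, _ = train_baseline(task, "source_only", train_cfg=self.TC)
        # flip every target label; the trained parameters must not change
        flipped = TransferTask(
            source=task.source,
            target=DomainDataset(
                [Trial(t.signal, 1 - t.label, t.subject_id, t.domain_id,
                       t.start_time) for t in task.target.trials],
                task.target.n_channels, task.target.sampling_rate,
                task.target.modality, task.target.species,
                task.target.domain_id),
            scenario=task.scenario, label_fraction=task.label_fraction)
        m2, _, _ = train_baseline(flipped, "source_only", train_cfg=self.TC)
        s1, s2 = m1.state_dict(), m2.state_dict()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])

    def test_comb_baseline_uses_both_pools(self):
        raw = easy_task(scenario="semi_supervised", l=20)
        task = prepare_task(raw, use_ea=False)
        model, test_pool, _ = train_baseline(task, "comb", train_cfg=self.TC)
        # test pool excludes the l% labeled target clips
        import math
        n_labeled = len(task.target) - len(test_pool)
        expected_labeled = 0
        for sid in task.target.subjects:
            trials = task.target.subject_trials(sid)
            for cls in (0, 1):
                n_cls = sum(t.label == cls for t in trials)
                expected_labeled += math.ceil(0.2 * n_cls)
        assert n_labeled == expected_labeled

    def test_scenario_config_errors(self):
        raw = easy_task()
        task = prepare_task(raw, use_ea=False)
        with pytest.raises(ValueError):
            train_baseline(task, "within", train_cfg=self.TC)
        with pytest.raises(ValueError):
            train_baseline(task, "nonsense", train_cfg=self.TC)
        with pytest.raises(ValueError):
            TransferTask(source=raw.source, target=raw.target,
                         scenario="unsupervised", label_fraction=10)

    def test_deterministic_training_is_bit_identical(self):
        task = prepare_task(easy_task(), use_ea=True)
        tc = TrainConfig(epochs=2, batch_size=16, seed=11, repeats=1)
        m1, _, _ = train_msa(task, train_cfg=tc)
        m2, _, _ = train_msa(task, train_cfg=tc)
        s1, s2 = m1.state_dict(), m2.state_dict()
        for k in s1:
            np.testing.assert_array_equal(s1[k], s2[k])


class TestRepeatedExperiment:
    def test_mean_std_match_hand_arithmetic_and_seeds(self):
        raw = easy_task()
        tc = TrainConfig(epochs=2, batch_size=16, seed=5, repeats=3)
        res = run_repeated_experiment(raw, MSA_METHOD, train_cfg=tc)
        assert res.seeds == [5, 6, 7]
        assert res.mean_auc == pytest.approx(np.mean(res.per_repeat_mean),
                                             abs=1e-12)
        assert res.std_auc == pytest.approx(np.std(res.per_repeat_mean),
                                            abs=1e-12)

    def test_single_repeat_has_zero_std(self):
        raw = easy_task()
        tc = TrainConfig(epochs=2, batch_size=16, seed=5, repeats=1)
        res = run_repeated_experiment(raw, MSA_METHOD, train_cfg=tc)
        assert res.std_auc == 0.0
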
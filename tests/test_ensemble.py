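import itertools

import numpy as np
import pytest

from incident_triage.base import OneVsRestTask, PairTask, PlattCalibrator
from incident_triage.ensemble import (
    EnsembleModel,
    LabelScheme,
    decompose_ovsa,
    decompose_ovso,
    load_ensemble,
    predict_dag,
    predict_ovsa,
    predict_voting,
    save_ensemble,
    train_ensemble,
)
from incident_triage.features import FeaturePipeline, build_vocabulary
from incident_triage.preprocessing import preprocess_corpus
from incident_triage.synthetic import generate_corpus

from conftest import FixedScoreEstimator, make_reports, stub_pair_model


def stub_voting_ensemble(scheme, outcomes):
    """Ensemble of constant-score pairwise stubs; ``outcomes[(a, b)]`` is the
    winning label for that pair."""
    models = {}
    for pair in scheme.pairs():
        winner = outcomes[(pair.a, pair.b)]
        models[pair] = stub_pair_model(pair.a, pair.b, 1.0 if winner == pair.a else -1.0)
    return models


def stub_ovsa_ensemble(scheme, probs):
    from incident_triage.base import BaseClassifierModel

    models = {}
    for lab in scheme.labels:
        p = probs[lab]
        # slope 0 would be invalid; encode the prob through the intercept
        score = np.log(p / (1 - p)) if 0 < p < 1 else (50.0 if p >= 1 else -50.0)
        models[OneVsRestTask(lab)] = BaseClassifierModel(
            task=OneVsRestTask(lab),
            algorithm="svm_linear",
            hyperparams={},
            positive_label=lab,
            negative_label=f"not_{lab}",
            estimator=FixedScoreEstimator(score),
            calibrator=PlattCalibrator(1.0, 0.0),
        )
    return models


ONE_X = np.zeros((1, 1))


class TestDecomposeOvso:
    def test_four_classes_six_subsets(self, four_scheme):
        reports = make_reports(["A", "B", "C", "D"] * 3)
        subsets = decompose_ovso(four_scheme, reports)
        assert len(subsets) == 6
        for task, members in subsets:
            labels = {r.incident_type for r in members}
            assert labels == {task.a, task.b}

    def test_eleven_classes_55_subsets(self):
        labels = [f"t{i:02d}" for i in range(11)]
        scheme = LabelScheme(tuple(labels))
        subsets = decompose_ovso(scheme, make_reports(labels * 2))
        assert len(subsets) == 55

    def test_missing_label_named(self, four_scheme):
        reports = make_reports(["A", "B", "C"])
        with pytest.raises(ValueError, match="D"):
            decompose_ovso(four_scheme, reports)


class TestDecomposeOvsa:
    def test_eleven_class_even_negatives(self):
        labels = [f"t{i:02d}" for i in range(11)]
        scheme = LabelScheme(tuple(labels))
        reports = make_reports(labels * 260)
        subsets = decompose_ovsa(scheme, reports, per_class_n=260, seed=0)
        assert len(subsets) == 11
        for task, pos, neg in subsets:
            assert len(pos) == 260 and len(neg) == 260
            per_lab = {}
            for r in neg:
                per_lab[r.incident_type] = per_lab.get(r.incident_type, 0) + 1
            assert set(per_lab.values()) == {26}
            assert task.label not in per_lab

    def test_round_robin_remainder(self, four_scheme):
        reports = make_reports(["A", "B", "C", "D"] * 290)
        subsets = decompose_ovsa(four_scheme, reports, per_class_n=290, seed=1)
        for task, pos, neg in subsets:
            per_lab = {}
            for r in neg:
                per_lab[r.incident_type] = per_lab.get(r.incident_type, 0) + 1
            rest = [lab for lab in four_scheme.labels if lab != task.label]
            # 290 = 96*3 + 2 -> first two rest labels get 97
            assert [per_lab[lab] for lab in rest] == [97, 97, 96]

    def test_seeded_and_deterministic(self, four_scheme):
        reports = make_reports(["A", "B", "C", "D"] * 30)
        a = decompose_ovsa(four_scheme, reports, per_class_n=20, seed=5)
        b = decompose_ovsa(four_scheme, reports, per_class_n=20, seed=5)
        c = decompose_ovsa(four_scheme, reports, per_class_n=20, seed=6)
        ids = lambda ss: [[r.report_id for r in s[1] + s[2]] for s in ss]  # noqa: E731
        assert ids(a) == ids(b)
        assert ids(a) != ids(c)

    def test_insufficient_reports_reports_shortfall(self, four_scheme):
        reports = make_reports(["A"] * 5 + ["B", "C", "D"] * 20)
        with pytest.raises(ValueError, match="A"):
            decompose_ovsa(four_scheme, reports, per_class_n=20)


class TestTrainEnsemble:
    def _fit(self, tiny_config, strategy, decision, algorithm="logreg"):
        corpus = generate_corpus(tiny_config)
        scheme = LabelScheme(tiny_config.label_scheme)
        docs = preprocess_corpus(corpus)
        pipeline = FeaturePipeline(vocab=build_vocabulary(docs), weighting="tf")
        if strategy == "ovso":
            subsets = decompose_ovso(scheme, corpus)
        else:
            subsets = decompose_ovsa(scheme, corpus, per_class_n=20, seed=0)
        return train_ensemble(
            subsets,
            algorithm=algorithm,
            strategy=strategy,
            decision=decision,
            scheme=scheme,
            pipeline=pipeline,
            preprocess=preprocess_corpus,
        )

    def test_ovso_model_count(self, tiny_config):
        ens = self._fit(tiny_config, "ovso", "voting")
        assert len(ens.base_models) == 3  # l=3 -> 3 pairs

    def test_ovsa_model_count(self, tiny_config):
        ens = self._fit(tiny_config, "ovsa", "argmax_prob")
        assert len(ens.base_models) == 3

    def test_dag_with_ovsa_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="dag"):
            self._fit(tiny_config, "ovsa", "dag")

    def test_separable_corpus_recovered(self, tiny_config):
        corpus = generate_corpus(tiny_config)
        docs = preprocess_corpus(corpus)
        for strategy, decision in (("ovso", "voting"), ("ovso", "dag"), ("ovsa", "argmax_prob")):
            ens = self._fit(tiny_config, strategy, decision)
            preds = ens.predict_docs(docs)
            gold = [r.incident_type for r in corpus]
            assert np.mean([p == g for p, g in zip(preds, gold)]) == 1.0

    def test_roundtrip_persistence(self, tiny_config, tmp_path):
        ens = self._fit(tiny_config, "ovso", "dag")
        save_ensemble(ens, tmp_path / "bundle")
        loaded = load_ensemble(tmp_path / "bundle")
        corpus = generate_corpus(tiny_config)
        docs = preprocess_corpus(corpus)
        assert loaded.predict_docs(docs) == ens.predict_docs(docs)
        assert loaded.scheme == ens.scheme


class TestVoting:
    def test_tally_example(self, four_scheme):
        outcomes = {
            ("A", "B"): "A", ("A", "C"): "A", ("A", "D"): "A",
            ("B", "C"): "B", ("C", "D"): "C", ("B", "D"): "B",
        }
        ens = EnsembleModel(
            scheme=four_scheme, strategy="ovso", decision="voting",
            base_models=stub_voting_ensemble(four_scheme, outcomes),
        )
        assert predict_voting(ens, ONE_X) == ["A"]

    def test_true_class_wins_strictly_when_its_contests_correct(self, four_scheme):
        """If all l-1 contests involving the gold label are won, no rival can tie."""
        for gold in four_scheme.labels:
            outcomes = {}
            for pair in four_scheme.pairs():
                if gold in (pair.a, pair.b):
                    outcomes[(pair.a, pair.b)] = gold
                else:
                    outcomes[(pair.a, pair.b)] = pair.b  # adversarial fill
            ens = EnsembleModel(
                scheme=four_scheme, strategy="ovso", decision="voting",
                base_models=stub_voting_ensemble(four_scheme, outcomes),
            )
            assert predict_voting(ens, ONE_X) == [gold]

    def test_tie_breaks_deterministically(self, four_scheme):
        # cyclic outcomes: A>B, B>C, C>A; D loses all -> three-way tie at 2 votes
        outcomes = {
            ("A", "B"): "A", ("B", "C"): "B", ("A", "C"): "C",
            ("A", "D"): "A", ("B", "D"): "B", ("C", "D"): "C",
        }
        models = stub_voting_ensemble(four_scheme, outcomes)
        ens = EnsembleModel(
            scheme=four_scheme, strategy="ovso", decision="voting", base_models=models
        )
        first = predict_voting(ens, ONE_X)
        assert all(predict_voting(ens, ONE_X) == first for _ in range(3))
        # equal summed probabilities -> falls back to scheme order -> A
        assert first == ["A"]

    def test_vote_tally_matches_bruteforce_recount(self, four_scheme):
        rng = np.random.default_rng(8)
        for _ in range(20):
            outcomes = {
                (p.a, p.b): (p.a if rng.random() < 0.5 else p.b)
                for p in four_scheme.pairs()
            }
            ens = EnsembleModel(
                scheme=four_scheme, strategy="ovso", decision="voting",
                base_models=stub_voting_ensemble(four_scheme, outcomes),
            )
            # brute-force recount
            tally = {lab: 0 for lab in four_scheme.labels}
            for winner in outcomes.values():
                tally[winner] += 1
            top = max(tally.values())
            winners = [lab for lab in four_scheme.labels if tally[lab] == top]
            assert predict_voting(ens, ONE_X)[0] in winners

    def test_wrong_scheme_rejected(self, four_scheme):
        ens = EnsembleModel(
            scheme=four_scheme, strategy="ovso", decision="dag",
            base_models=stub_voting_ensemble(
                four_scheme, {(p.a, p.b): p.a for p in four_scheme.pairs()}
            ),
        )
        with pytest.raises(ValueError):
            predict_voting(ens, ONE_X)


class TestDag:
    def test_sac_traversal(self, sac_scheme):
        # SAC4 rejected at root, then SAC1 rejected, then SAC3 beats SAC2
        outcomes = {
            ("SAC1", "SAC4"): "SAC1",
            ("SAC1", "SAC3"): "SAC3",
            ("SAC2", "SAC3"): "SAC3",
            # remaining contests never reached; fill arbitrarily
            ("SAC1", "SAC2"): "SAC1",
            ("SAC2", "SAC4"): "SAC2",
            ("SAC3", "SAC4"): "SAC3",
        }
        ens = EnsembleModel(
            scheme=sac_scheme, strategy="ovso", decision="dag",
            base_models=stub_voting_ensemble(sac_scheme, outcomes),
        )
        assert predict_dag(ens, ONE_X) == ["SAC3"]

    def test_exactly_l_minus_1_evaluations(self, four_scheme):
        outcomes = {(p.a, p.b): p.a for p in four_scheme.pairs()}
        ens = EnsembleModel(
            scheme=four_scheme, strategy="ovso", decision="dag",
            base_models=stub_voting_ensemble(four_scheme, outcomes),
        )
        ens.dag_eval_count = 0
        predict_dag(ens, ONE_X)
        assert ens.dag_eval_count == 3
        predict_dag(ens, np.zeros((5, 1)))
        assert ens.dag_eval_count == 3 + 5 * 3

    def test_exhaustive_soundness_l4(self, four_scheme):
        """Over all 2^6 pairwise-outcome assignments: whenever the three
        contests involving the gold label are won, the DAG returns it."""
        pairs = four_scheme.pairs()
        for gold in four_scheme.labels:
            for bits in itertools.product([0, 1], repeat=6):
                outcomes = {
                    (p.a, p.b): (p.a if b else p.b) for p, b in zip(pairs, bits)
                }
                if any(
                    outcomes[(p.a, p.b)] != gold
                    for p in pairs
                    if gold in (p.a, p.b)
                ):
                    continue
                ens = EnsembleModel(
                    scheme=four_scheme, strategy="ovso", decision="dag",
                    base_models=stub_voting_ensemble(four_scheme, outcomes),
                )
                assert predict_dag(ens, ONE_X) == [gold]

    def test_missing_pair_model_error(self, four_scheme):
        models = stub_voting_ensemble(
            four_scheme, {(p.a, p.b): p.a for p in four_scheme.pairs()}
        )
        bad = dict(models)
        moved = bad.pop(PairTask("A", "D"))
        bad[PairTask("D", "A")] = moved  # wrong orientation
        ens = EnsembleModel(
            scheme=four_scheme, strategy="ovso", decision="dag", base_models=bad
        )
        with pytest.raises(ValueError, match="missing"):
            predict_dag(ens, ONE_X)


class TestOvsaPredict:
    def test_argmax(self, four_scheme):
        ens = EnsembleModel(
            scheme=four_scheme, strategy="ovsa", decision="argmax_prob",
            base_models=stub_ovsa_ensemble(
                four_scheme, {"A": 0.9, "B": 0.2, "C": 0.1, "D": 0.3}
            ),
        )
        assert predict_ovsa(ens, ONE_X) == ["A"]

    def test_all_equal_first_label(self, four_scheme):
        ens = EnsembleModel(
            scheme=four_scheme, strategy="ovsa", decision="argmax_prob",
            base_models=stub_ovsa_ensemble(
                four_scheme, {lab: 0.5 for lab in four_scheme.labels}
            ),
        )
        assert predict_ovsa(ens, ONE_X) == ["A"]

    def test_matches_bruteforce_max(self, four_scheme):
        rng = np.random.default_rng(9)
        for _ in range(20):
            probs = {lab: float(rng.uniform(0.05, 0.95)) for lab in four_scheme.labels}
            ens = EnsembleModel(
                scheme=four_scheme, strategy="ovsa", decision="argmax_prob",
                base_models=stub_ovsa_ensemble(four_scheme, probs),
            )
            expected = max(four_scheme.labels, key=lambda lab: probs[lab])
            assert predict_ovsa(ens, ONE_X) == [expected]


class TestModelCountInvariant:
    @pytest.mark.parametrize("l", [2, 4, 11])
    def test_counts(self, l):
        labels = tuple(f"c{i}" for i in range(l))
        scheme = LabelScheme(labels)
        assert len(scheme.pairs()) == l * (l - 1) // 2
        with pytest.raises(ValueError):
            EnsembleModel(
                scheme=scheme, strategy="ovso", decision="voting", base_models={}
            )
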
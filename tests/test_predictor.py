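"""Balanced training sets, classifier bank, cross-validation."""

import pytest

from microtraits.corpus_io import TrainingInstance
from microtraits.predictor import (
    analyze,
    build_balanced_training_sets,
    cross_validate,
    macro_average,
    predict_characters,
    train_classifiers,
)


def _inst(text, cid):
    return TrainingInstance(text, cid)


@pytest.fixture(scope="module")
def toy_instances():
    insts = []
    for i in range(12):
        insts.append(_inst(f"DNA G + C content is {30 + i}.5 mol%.",
                           "gc_content"))
        insts.append(_inst(f"Cells are motile in medium {i}.", "motility"))
        insts.append(_inst(f"Colonies are convex on plate {i}.",
                           "colony_shape"))
    return insts


class TestBalancedSets:
    def test_counts_balance(self, toy_instances):
        sets = build_balanced_training_sets(toy_instances, seed=1)
        for ts in sets.values():
            assert len(ts.positives) == len(ts.negatives)
            assert not set(ts.positives) & set(ts.negatives)

    def test_negatives_drawn_from_other_sentences(self, toy_instances):
        sets = build_balanced_training_sets(toy_instances, seed=1)
        gc = sets["gc_content"]
        assert all("mol%" not in t for t in gc.negatives)

    def test_shortfall_takes_entire_pool(self, caplog):
        insts = [_inst(f"sentence number {i} mentions spores.",
                       "internal_features") for i in range(5)]
        insts.append(_inst("Cells are motile.", "motility"))
        sets = build_balanced_training_sets(insts, seed=0)
        assert sets["internal_features"].negatives == ["Cells are motile."]

    def test_seed_determinism_and_sensitivity(self, toy_instances):
        a = build_balanced_training_sets(toy_instances, seed=5)
        b = build_balanced_training_sets(toy_instances, seed=5)
        c = build_balanced_training_sets(toy_instances, seed=6)
        assert a["gc_content"].negatives == b["gc_content"].negatives
        assert any(a[k].negatives != c[k].negatives for k in a)


class TestFeaturizer:
    def test_numerals_mapped_to_placeholder(self):
        feats = analyze("Cells are 0.3–0.5 μm in diameter.")
        assert "NUM μm" in feats and "in diameter" in feats
        assert all("0.3" not in f for f in feats)

    def test_identical_sentences_identical_features(self):
        s = "Growth occurs at pH 6–8."
        assert analyze(s) == analyze(s)

    def test_vocabulary_built_on_training_split_only(self):
        from microtraits.predictor import Featurizer

        fz = Featurizer().fit(["cells are motile", "colonies are convex"])
        narrow = set(fz.vocabulary)
        wide = set(Featurizer().fit(
            ["cells are motile", "colonies are convex",
             "spores are observed"]
        ).vocabulary)
        assert narrow < wide
        # unseen tokens are ignored at predict time
        x = fz.transform(["endospores were detected"])
        assert x.sum() == 0


class TestTraining:
    def test_separable_toy_set_fits_perfectly(self, toy_instances):
        sets = build_balanced_training_sets(toy_instances, seed=1)
        bank = train_classifiers(sets, seed=1)
        for inst in toy_instances:
            assert inst.character_id in predict_characters(
                bank, inst.sentence_text
            )

    def test_retraining_reproduces_predictions(self, toy_instances):
        sets = build_balanced_training_sets(toy_instances, seed=1)
        probe = [i.sentence_text for i in toy_instances]
        p1 = [predict_characters(train_classifiers(sets, seed=1), t)
              for t in probe]
        p2 = [predict_characters(train_classifiers(sets, seed=1), t)
              for t in probe]
        assert p1 == p2

    def test_multi_label_width_and_length(self, small_corpus):
        _, _, insts = small_corpus
        bank = train_classifiers(build_balanced_training_sets(insts, 7), 7)
        got = predict_characters(
            bank, "Cells are 0.3–0.5 μm wide and 8.0–15.0 μm long."
        )
        assert {"cell_width", "cell_length"} <= got

    def test_gibberish_sentence_routed_nowhere(self, small_corpus):
        _, _, insts = small_corpus
        bank = train_classifiers(build_balanced_training_sets(insts, 7), 7)
        assert predict_characters(bank, "of the and a") == set()

    def test_removing_a_model_leaves_others_unchanged(self, toy_instances):
        sets = build_balanced_training_sets(toy_instances, seed=1)
        bank = train_classifiers(sets, seed=1)
        full = predict_characters(bank, "Cells are motile in medium 3.")
        del bank.models["gc_content"]
        assert predict_characters(
            bank, "Cells are motile in medium 3."
        ) == full - {"gc_content"}


class TestCrossValidation:
    def test_separable_corpus_cross_validates_perfectly(self, toy_instances):
        reports = cross_validate(toy_instances, k=4, seed=7)
        assert {r.character_id for r in reports} == {
            "gc_content", "motility", "colony_shape"
        }
        mp, mr = macro_average(reports)
        assert mp == 1.0 and mr == 1.0

    def test_precision_recall_bounded(self, toy_instances):
        for r in cross_validate(toy_instances, k=3, seed=1):
            assert 0.0 <= r.precision <= 1.0 and 0.0 <= r.recall <= 1.0

    def test_k_larger_than_dataset_raises(self, toy_instances):
        with pytest.raises(ValueError):
            cross_validate(toy_instances[:4], k=50, seed=0)

    def test_k_below_two_raises(self, toy_instances):
        with pytest.raises(ValueError):
            cross_validate(toy_instances, k=1, seed=0)
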
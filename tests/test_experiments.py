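"""Scoring rules, experiment configuration, and protocol reproducibility."""
import numpy as np
import pytest

from cinet.experiments import (NOISE_GRID, TRAIN_WORDS_3, TRAIN_WORDS_5,
                               ExperimentSpec, derive_seed, run_set,
                               score_ambiguous_contextfree, score_contextual,
                               standard_spec)
from cinet.network import TrainConfig
from cinet.stimuli import TARGET_LETTERS


class TestScoring:
    def test_contextfree_counts_both_parents(self):
        a, h, o = (TARGET_LETTERS.index(c) for c in "AHO")
        assert score_ambiguous_contextfree(a, ("A", "H")) == 1
        assert score_ambiguous_contextfree(h, ("A", "H")) == 1
        assert score_ambiguous_contextfree(o, ("A", "H")) == 0

    def test_contextual_requires_the_implied_parent(self):
        a, h, p = (TARGET_LETTERS.index(c) for c in "AHP")
        assert score_contextual(a, "A") == 1
        assert score_contextual(h, "A") == 0  # the other parent is wrong here
        assert score_contextual(p, "A") == 0

    def test_uniform_decisions_score_one_third(self):
        """2 of 6 classes count: long-run mean of random decisions -> 1/3."""
        rng = np.random.default_rng(0)
        n = 6000
        scores = [score_ambiguous_contextfree(d, ("A", "H"))
                  for d in rng.integers(0, 6, size=n)]
        p = np.mean(scores)
        assert abs(p - 1 / 3) < 3 * np.sqrt((1 / 3) * (2 / 3) / n)


class TestSeeds:
    def test_derive_seed_is_stable_and_bounded(self):
        s1 = derive_seed(42, "eval", "2", 0)
        assert s1 == derive_seed(42, "eval", "2", 0)
        assert 0 <= s1 < 2**31
        assert s1 != derive_seed(42, "eval", "2", 1)
        assert s1 != derive_seed(43, "eval", "2", 0)


class TestSpecValidation:
    def test_standard_specs_cover_all_sets(self):
        for sid, span in [("1", 0), ("2", 2), ("3", 4), ("4A", 4),
                          ("4B", 4), ("5", 4), ("6", 2)]:
            spec = standard_spec(sid, "ambiguous")
            assert spec.span == span
            assert spec.noise_grid == NOISE_GRID

    def test_unknown_set_rejected(self):
        with pytest.raises(ValueError):
            standard_spec("7", "ambiguous")

    def test_word_span_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ExperimentSpec(set_id="2", s1=2, s2=2, train_words=TRAIN_WORDS_3,
                           test_center="ambiguous", context_mode="congruent")

    def test_word_center_letter_checked(self):
        words = ("ABG",) + TRAIN_WORDS_3[1:]  # class-A word without A in the middle
        with pytest.raises(ValueError):
            ExperimentSpec(set_id="2", s1=1, s2=1, train_words=words,
                           test_center="ambiguous", context_mode="congruent")

    def test_weighted_mode_needs_weights(self):
        with pytest.raises(ValueError):
            ExperimentSpec(set_id="4A", s1=2, s2=2, train_words=TRAIN_WORDS_5,
                           test_center="ambiguous", context_mode="weighted")

    def test_negative_noise_grid_rejected(self):
        with pytest.raises(ValueError):
            ExperimentSpec(set_id="1", s1=0, s2=0, train_words=None,
                           test_center="ambiguous", context_mode="none",
                           noise_grid=(-0.5,))


@pytest.fixture(scope="module")
def micro_spec():
    """Context-free set at toy scale: 1 network, relaxed stop, 2 noise levels."""
    return ExperimentSpec(
        set_id="1", s1=0, s2=0, train_words=None, test_center="ambiguous",
        context_mode="none", noise_grid=(0.1, 1.0), n_networks=1, n_samples=8,
        seed=11, train_config=TrainConfig(samples_per_class=4, loss_threshold=0.05,
                                          max_epochs=60))


class TestRunSet:
    def test_reproducible_from_the_global_seed(self, micro_spec):
        r1 = run_set(micro_spec)
        r2 = run_set(micro_spec)
        assert np.array_equal(r1.scores, r2.scores)
        assert r1.manifest["train_final_loss"] == r2.manifest["train_final_loss"]

    def test_result_table_shape_and_range(self, micro_spec):
        res = run_set(micro_spec)
        assert res.scores.shape == (3, 2, 1, 8)  # items x sigma2 x nets x samples
        assert set(np.unique(res.scores)) <= {0, 1}
        row = res.row()
        assert ((0 <= row) & (row <= 1)).all()
        # two-stage averaging: table entry equals the mean of per-item means
        assert np.allclose(row, res.per_item().to_numpy().mean(axis=0))
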
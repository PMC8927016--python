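"""Loss closed forms, the early-stopping protocol, and optimization sanity."""

import numpy as np
import pandas as pd
import pytest

from ignet.data_io import stratified_split
from ignet.model import ModelConfig
from ignet.snp_selection import SelectedPanel, append_apoe
from ignet.synthetic import SimConfig, simulate_cohort
from ignet.training import (EarlyStopping, OptimizerConfig, TrainingData,
                            cross_entropy_loss, predict, train)


class TestCrossEntropy:
    def test_certain_correct_prediction_gives_zero(self):
        scores = np.array([[100.0, 0.0], [0.0, 100.0]])
        assert cross_entropy_loss(scores, [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_even_odds_give_ln2(self):
        scores = np.zeros((3, 2))
        assert cross_entropy_loss(scores, [0, 1, 0]) == pytest.approx(np.log(2))

    def test_mean_reduction_over_batch(self):
        a = cross_entropy_loss(np.array([[2.0, 0.0]]), [0])
        b = cross_entropy_loss(np.array([[0.0, 3.0]]), [0])
        both = cross_entropy_loss(np.array([[2.0, 0.0], [0.0, 3.0]]), [0, 0])
        assert both == pytest.approx((a + b) / 2)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cross_entropy_loss(np.empty((0, 2)), [])


class TestEarlyStopping:
    def test_reference_sequence_stops_after_epoch_five(self):
        """Losses 0.70, 0.60, 0.61, 0.62, 0.63 with patience 3: the counter
        fills on epochs 3-5 and the epoch-2 snapshot is the best."""
        stopper = EarlyStopping(patience=3)
        stopped_at = None
        for epoch, loss in enumerate([0.70, 0.60, 0.61, 0.62, 0.63], start=1):
            stopper.update(loss, epoch)
            if stopper.should_stop:
                stopped_at = epoch
                break
        assert stopped_at == 5
        assert stopper.best_epoch == 2
        assert stopper.best == 0.60

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        for epoch, loss in enumerate([0.5, 0.6, 0.4], start=1):
            stopper.update(loss, epoch)
        assert stopper.since_improvement == 0
        assert not stopper.should_stop

    def test_sub_tolerance_improvement_does_not_count(self):
        stopper = EarlyStopping(patience=1, min_delta=1e-6)
        stopper.update(0.5, 1)
        assert not stopper.update(0.5 - 1e-8, 2)
        assert stopper.should_stop


@pytest.fixture(scope="module")
def genetic_setup():
    """Small cohort with clear genetic signal; genetic-only configs train in
    well under a second."""
    config = SimConfig(n_subjects=120, n_ad_target=55, n_snps=60,
                       causal_log_odds=1.5, apoe_log_odds=1.5, seed=21)
    cohort = simulate_cohort(config)
    split = stratified_split(cohort.labels, seed=21)
    panel = append_apoe(SelectedPanel(
        snp_ids=[cohort.genotypes.snp_ids[j] for j in cohort.truth["causal_indices"]],
        p_values=[1e-6] * len(cohort.truth["causal_indices"])))
    data = TrainingData.from_cohort(cohort, panel)
    model_config = ModelConfig(variant="genetic_only", seq_len=len(panel),
                               volume_shape=(32, 32, 32))
    return data, split, model_config


class TestTrainLoop:
    def test_identical_seeds_reproduce_loss_histories(self, genetic_setup):
        data, split, mc = genetic_setup
        _, s1 = train(data, split, mc, max_epochs=5, seed=4)
        _, s2 = train(data, split, mc, max_epochs=5, seed=4)
        assert s1.train_loss_history == s2.train_loss_history
        assert s1.val_loss_history == s2.val_loss_history

    def test_different_seed_changes_history(self, genetic_setup):
        data, split, mc = genetic_setup
        _, s1 = train(data, split, mc, max_epochs=3, seed=4)
        _, s2 = train(data, split, mc, max_epochs=3, seed=5)
        assert s1.train_loss_history != s2.train_loss_history

    def test_returned_snapshot_achieves_best_val_loss(self, genetic_setup):
        data, split, mc = genetic_setup
        model, state = train(data, split, mc, max_epochs=10, seed=1)
        assert state.best_val_loss == pytest.approx(min(state.val_loss_history))
        assert state.epoch <= state.max_epochs
        # recompute the val loss of the returned parameters in eval mode
        from ignet.training import _batch_scores, _partition_indices
        parts = _partition_indices(data, split)
        scores = _batch_scores(model, data, parts["val"])
        recomputed = cross_entropy_loss(scores, data.labels[parts["val"]])
        assert recomputed == pytest.approx(state.best_val_loss, abs=1e-9)

    def test_histories_grow_one_entry_per_epoch(self, genetic_setup):
        data, split, mc = genetic_setup
        _, state = train(data, split, mc, max_epochs=6, patience=100, seed=0)
        assert len(state.train_loss_history) == state.epoch == 6
        assert len(state.val_loss_history) == 6

    def test_strong_signal_is_learned(self, genetic_setup):
        """Labels carry irreducible liability noise, so perfect training
        accuracy is unattainable; the fit must still clearly beat the
        majority class."""
        data, split, mc = genetic_setup
        model, state = train(data, split, mc, max_epochs=25, patience=25, seed=2)
        train_idx = np.array([i for i, s in enumerate(data.subject_ids)
                              if split[s] == "train"])
        preds = predict(model, data, train_idx)
        acc = ((preds["p_ad"] >= 0.5).astype(int) == preds["label"]).mean()
        majority = max(preds["label"].mean(), 1 - preds["label"].mean())
        assert acc >= 0.75 > majority + 0.1
        assert state.train_loss_history[-1] < 0.55

    def test_separable_multimodal_cohort_reaches_high_training_accuracy(self):
        """Large effects in both modalities: the full model must fit its
        training partition nearly perfectly."""
        config = SimConfig(n_subjects=200, n_ad_target=92, n_snps=40,
                           causal_log_odds=2.0, apoe_log_odds=2.0,
                           atrophy_effect=0.6, roi_between_sd=0.1,
                           coupling=0.0, seed=33)
        cohort = simulate_cohort(config)
        split = stratified_split(cohort.labels, seed=33)
        panel = append_apoe(SelectedPanel(
            snp_ids=[cohort.genotypes.snp_ids[j]
                     for j in cohort.truth["causal_indices"]],
            p_values=[1e-6] * len(cohort.truth["causal_indices"])))
        data = TrainingData.from_cohort(cohort, panel)
        mc = ModelConfig(variant="full", seq_len=len(panel),
                         volume_shape=(32, 32, 32))
        model, _ = train(data, split, mc, max_epochs=25, patience=25, seed=3)
        train_idx = np.array([i for i, s in enumerate(data.subject_ids)
                              if split[s] == "train"])
        preds = predict(model, data, train_idx)
        acc = ((preds["p_ad"] >= 0.5).astype(int) == preds["label"]).mean()
        assert acc >= 0.95

    def test_label_permutation_gives_chance_test_accuracy(self, genetic_setup):
        """Training on permuted labels must not transfer: pooled test
        accuracy over permutation replicates stays in the 95% binomial band
        around one half (large test fraction for statistical power)."""
        data, _, mc = genetic_setup
        labels = pd.Series(data.labels,
                           index=pd.Index(data.subject_ids, name="subject_id"))
        split = stratified_split(labels, fractions=(0.5, 0.1, 0.4), seed=21)
        test_idx = np.array([i for i, s in enumerate(data.subject_ids)
                             if split[s] == "test"])
        rng = np.random.default_rng(9)
        correct = total = 0
        for rep in range(2):
            shuffled = TrainingData(
                subject_ids=data.subject_ids,
                labels=rng.permutation(data.labels),
                volumes=data.volumes, tokens=data.tokens,
                apoe_position=data.apoe_position)
            model, _ = train(shuffled, split, mc, max_epochs=10, seed=7 + rep)
            preds = predict(model, shuffled, test_idx)
            correct += ((preds["p_ad"] >= 0.5).astype(int)
                        == preds["label"]).sum()
            total += len(preds)
        acc = correct / total
        half_width = 1.96 * 0.5 / np.sqrt(total)
        assert 0.5 - half_width - 1e-9 <= acc <= 0.5 + half_width + 1e-9

    def test_empty_partition_rejected(self, genetic_setup):
        data, _, mc = genetic_setup
        bad_split = pd.Series("train", index=pd.Index(data.subject_ids,
                                                      name="subject_id"))
        with pytest.raises(ValueError, match="non-empty"):
            train(data, bad_split, mc, max_epochs=2, seed=0)


class TestOptimizerConfig:
    def test_defaults_match_protocol(self):
        cfg = OptimizerConfig()
        assert (cfg.beta1, cfg.beta2, cfg.epsilon) == (0.9, 0.999, 1e-8)
        assert cfg.learning_rate == 1e-3 and cfg.batch_size == 16

    def test_invalid_betas_rejected(self):
        with pytest.raises(ValueError, match="betas"):
            OptimizerConfig(beta1=1.0)
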
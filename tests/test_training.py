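"""Training loop contracts: minibatch assembly and positive-pair structure,
determinism, early stopping, obsNum semantics, ablation paths."""

import numpy as np
import pytest

from leopard import LossWeights, NetworkConfig, TrainingConfig, fit, split_dataset
from leopard.errors import ConfigError
from leopard.training import Trainer


def small_net():
    return NetworkConfig(embed_dim=16, encoder_layers=2, generator_layers=2,
                         discriminator_width=32)


@pytest.fixture
def trainer(small_dataset):
    ds, _ = small_dataset
    split = split_dataset(ds, (0.64, 0.16, 0.20), 7)
    cfg = TrainingConfig(batch_size=16, max_epochs=3, seed=7)
    return Trainer(ds, split, ("v2", "t2"), cfg, small_net(), LossWeights())


def test_pair_families_for_two_by_two(trainer):
    """Content pairs: same view across timepoints (generated block standing in
    for the missing class); temporal pairs: same timepoint across views."""
    assert set(trainer.content_pair_families) == {
        (("v1", "t1"), ("v1", "t2")),
        (("v2", "t1"), ("v2", "t2")),
    }
    assert set(trainer.temporal_pair_families) == {
        (("v1", "t1"), ("v2", "t1")),
        (("v1", "t2"), ("v2", "t2")),
    }
    assert trainer.generated_classes == [("v2", "t2")]
    assert trainer.gen_sources[("v2", "t2")] == ((("v2", "t1")), ("v1", "t2"))


def test_minibatch_alignment(trainer):
    batch = trainer.assemble_minibatch(np.arange(16))
    assert all(cd.x.shape[0] == 16 for cd in batch.classes.values())


def test_train_step_deterministic(small_dataset):
    ds, _ = small_dataset
    split = split_dataset(ds, (0.64, 0.16, 0.20), 7)

    def one_epoch():
        tr = Trainer(ds, split, ("v2", "t2"),
                     TrainingConfig(batch_size=16, max_epochs=1, seed=3),
                     small_net(), LossWeights())
        return tr.train_step(tr.assemble_minibatch(np.arange(16)))

    assert one_epoch() == one_epoch()


def test_fit_reproducible_and_history_bounded(small_dataset):
    ds, _ = small_dataset
    split = split_dataset(ds, (0.64, 0.16, 0.20), 7)
    cfg = TrainingConfig(batch_size=16, max_epochs=4, seed=5)
    m1, h1 = fit(ds, split, ("v2", "t2"), cfg, small_net(), LossWeights())
    m2, h2 = fit(ds, split, ("v2", "t2"), cfg, small_net(), LossWeights())
    assert len(h1) <= 4
    assert h1 == h2
    for a, b in zip(m1.get_state(), m2.get_state()):
        assert np.array_equal(a, b)


def test_validation_loss_improves_with_training(small_dataset):
    ds, _ = small_dataset
    split = split_dataset(ds, (0.64, 0.16, 0.20), 7)
    _, hist = fit(ds, split, ("v2", "t2"),
                  TrainingConfig(batch_size=16, max_epochs=40, seed=1),
                  small_net(), LossWeights())
    assert hist[-1]["val_mse"] < hist[0]["val_mse"]


def test_early_stopping_returns_best_checkpoint(small_dataset):
    ds, _ = small_dataset
    split = split_dataset(ds, (0.64, 0.16, 0.20), 7)
    trainer = Trainer(ds, split, ("v2", "t2"),
                      TrainingConfig(batch_size=16, max_epochs=25, seed=2,
                                     early_stop_patience=5),
                      small_net(), LossWeights())
    model, hist = trainer.fit()
    best = min(h["val_mse"] for h in hist)
    trainer.model.set_state(model.get_state())
    assert trainer.validation_reconstruction_mse() == pytest.approx(best,
                                                                    rel=1e-9)


def test_obs_num_zero_excludes_target_rows(trainer):
    target_data = trainer.train_data[("v2", "t2")]
    assert not target_data.row_observed.any()


def test_obs_num_reveals_exact_rows(small_dataset):
    ds, _ = small_dataset
    split = split_dataset(ds, (0.64, 0.16, 0.20), 7)
    tr = Trainer(ds, split, ("v2", "t2"),
                 TrainingConfig(batch_size=16, max_epochs=1, seed=3, obs_num=9),
                 small_net(), LossWeights())
    assert tr.train_data[("v2", "t2")].row_observed.sum() == 9


def test_ablation_path_without_adversary(small_dataset):
    """With w_adv = 0 and the discriminator frozen, the trajectory is a pure
    reconstruction + contrastive + representation descent and D never moves."""
    ds, _ = small_dataset
    split = split_dataset(ds, (0.64, 0.16, 0.20), 7)
    cfg = TrainingConfig(batch_size=16, max_epochs=2, seed=4,
                         update_discriminator=False)
    weights = LossWeights(w_rec=1.0, w_con=0.1, w_rep=0.1, w_adv=0.0)
    tr = Trainer(ds, split, ("v2", "t2"), cfg, small_net(), weights)
    d_before = [p.data.copy() for p in tr.model.discriminator_parameters()]
    _, hist = tr.fit()
    d_after = [p.data for p in tr.model.discriminator_parameters()]
    for a, b in zip(d_before, d_after):
        assert np.array_equal(a, b)
    assert all(np.isnan(h["d"]) for h in hist)


def test_empty_training_split_rejected(small_dataset):
    ds, _ = small_dataset
    split = split_dataset(ds, (0.64, 0.16, 0.20), 7)
    split.train_ids = []
    with pytest.raises(ConfigError):
        Trainer(ds, split, ("v2", "t2"), TrainingConfig(), small_net(),
                LossWeights())


def test_additional_training_timepoints_improve_completion():
    """Completing (v2, t3) with no revealed rows: adding the baseline
    timepoint to training lowers percent bias on the held-out block."""
    import warnings

    from leopard import (
        LongitudinalDataset,
        NetworkConfig,
        SyntheticSpec,
        impute_missing_block,
        pb_report,
        simulate_dataset,
    )
    from leopard.data import DataBlock

    spec = SyntheticSpec(n_subjects=300, n_timepoints=3, seed=3)
    ds, _ = simulate_dataset(spec)
    split = split_dataset(ds, (0.64, 0.16, 0.20), 3)
    target = ("v2", "t3")
    tb = ds.blocks[target]
    rows = tb.row_indices(split.test_ids)
    truth_block = DataBlock(*target, list(split.test_ids),
                            list(tb.variable_ids), tb.values[rows],
                            tb.observed_mask[rows])
    eval_ds = LongitudinalDataset(
        {k: b for k, b in ds.blocks.items() if k != target},
        ds.sample_ids, ds.view_ids, ds.timepoint_ids, {target})
    medians = {}
    for tps in (["t2", "t3"], ["t1", "t2", "t3"]):
        cfg = TrainingConfig(seed=3, obs_num=0, max_epochs=120,
                             included_timepoints=tps)
        tr = Trainer(ds, split, target, cfg, NetworkConfig(), LossWeights())
        model, _ = tr.fit()
        imputed = impute_missing_block(eval_ds, target, model,
                                       sample_ids=split.test_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            medians[len(tps)] = pb_report(truth_block, imputed,
                                          "leopard").median()
    assert medians[3] < medians[2]


def test_three_timepoint_pair_structure():
    from leopard import SyntheticSpec, simulate_dataset

    spec = SyntheticSpec(n_subjects=40, n_variables=(8, 6), n_timepoints=3,
                         content_dim=3, private_dim=1, seed=9)
    ds, _ = simulate_dataset(spec)
    split = split_dataset(ds, (0.64, 0.16, 0.20), 1)
    tr = Trainer(ds, split, ("v2", "t1"),
                 TrainingConfig(batch_size=8, max_epochs=1, seed=1),
                 small_net(), LossWeights())
    # 3 timepoint pairs per view for content, one view pair per timepoint
    assert len(tr.content_pair_families) == 6
    assert len(tr.temporal_pair_families) == 3
    # the earlier-timepoint completion: content from the nearest timepoint
    assert tr.gen_sources[("v2", "t1")] == ((("v2", "t2")), ("v1", "t1"))
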
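import numpy as np
import pytest

from conftest import TINY_CONFIG
from mirtarget.model import ModelConfig, TargetModel, count_parameters
from mirtarget.synthetic import SyntheticSpec, generate_pairs
from mirtarget.trainer import Checkpoint, TrainConfig, bce_loss, predict_pair, train


class TestParameterCount:
    def test_reference_hyperparameters_give_published_total(self):
        assert count_parameters(ModelConfig.full()) == 26_691_717

    def test_toy_config_hand_summed(self):
        # embedding 20 + encoder layer 172 + transform 20 + convs 395 + bn 16 + head 2
        assert count_parameters(ModelConfig(d0=4, nl=1, nh=1, d1=4, ks=3)) == 625

    @pytest.mark.parametrize("d0,nl,d1,ks", [
        (4, 1, 4, 3), (4, 2, 8, 3), (8, 1, 4, 5), (8, 2, 8, 5),
    ])
    def test_closed_form_matches_instantiated_model(self, d0, nl, d1, ks):
        cfg = ModelConfig(d0=d0, nl=nl, nh=1, d1=d1, ks=ks, mirna_pad=6, cts_pad=9)
        model = TargetModel(cfg, seed=0)
        assert model.num_parameters() == count_parameters(cfg)

    def test_full_model_instantiation_matches_closed_form(self):
        model = TargetModel(ModelConfig.full(), seed=0)
        assert model.num_parameters() == 26_691_717


class TestForwardContracts:
    def test_predictions_are_probabilities_and_deterministic(self, tiny_model):
        pairs = [("AGCUAGCUAGCUAGCUAGCUAG", "UCGAUCGAUCGAU" + "A" * 40)]
        a = tiny_model.predict_batch(pairs)
        b = tiny_model.predict_batch(pairs)
        assert 0.0 < a[0] < 1.0
        np.testing.assert_array_equal(a, b)

    def test_probability_map_shape_matches_pads(self, tiny_model):
        probs, maps = tiny_model.predict_batch(
            [("AGCUAGCUAGCUAGCUAGCUAG", "AGCU" * 8)], return_maps=True)
        assert maps.shape == (1, TINY_CONFIG.mirna_pad, TINY_CONFIG.cts_pad)
        assert ((maps > 0) & (maps < 1)).all()

    def test_overlength_sequence_rejected(self, tiny_model):
        from mirtarget.seqio import LengthError

        with pytest.raises(LengthError):
            tiny_model.predict_batch([("A" * (TINY_CONFIG.mirna_pad + 1), "AGCU")])

    def test_bce_loss_matches_hand_formula(self):
        from mirtarget.nn import Tensor

        p = Tensor(np.array([0.9, 0.2]))
        y = np.array([1.0, 0.0])
        expected = -np.mean([np.log(0.9), np.log(0.8)])
        assert bce_loss(p, y).item() == pytest.approx(expected, rel=1e-5)


@pytest.fixture(scope="module")
def toy_sets():
    train_pairs = generate_pairs(SyntheticSpec(n_pairs=32, max_edits=0, rng_seed=31))
    val_pairs = generate_pairs(SyntheticSpec(n_pairs=16, max_edits=0, rng_seed=32))
    return train_pairs, val_pairs


class TestTraining:
    def test_loss_decreases_on_toy_set(self, toy_sets, tmp_path):
        train_pairs, val_pairs = toy_sets
        log = tmp_path / "log.tsv"
        train(train_pairs, val_pairs, TINY_CONFIG,
              TrainConfig(epochs=5, batch_size=16, learning_rate=2e-3, rng_seed=1234),
              log_path=log)
        from mirtarget.trainer import epoch_losses

        losses = epoch_losses(log)
        assert len(losses) == 5
        assert losses[-1] < losses[0]

    def test_seeded_training_is_reproducible(self, toy_sets):
        train_pairs, val_pairs = toy_sets
        cfg = TrainConfig(epochs=2, batch_size=16, learning_rate=1e-3, rng_seed=77)
        a = train(train_pairs, val_pairs, TINY_CONFIG, cfg)
        b = train(train_pairs, val_pairs, TINY_CONFIG, cfg)
        assert a.epoch == b.epoch
        ka = a.val_report.score if a.val_report.score is not None else a.val_report.accuracy
        kb = b.val_report.score if b.val_report.score is not None else b.val_report.accuracy
        assert ka == kb  # bitwise-identical selected-checkpoint validation score
        for name in a.weights:
            np.testing.assert_array_equal(a.weights[name], b.weights[name])

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            train([], [], TINY_CONFIG, TrainConfig(epochs=1))


class TestCheckpoint:
    def test_save_load_roundtrip_is_bitwise_stable(self, tiny_checkpoint, tmp_path):
        path = tmp_path / "model.ckpt"
        tiny_checkpoint.save(path)
        back = Checkpoint.load(path)
        assert back.epoch == tiny_checkpoint.epoch
        assert back.model_config == tiny_checkpoint.model_config
        pair = ("AGCUAGCUAGCUAGCUAGCUAG", "AGCU" * 10)
        p1, m1 = predict_pair(*pair, tiny_checkpoint)
        p2, m2 = predict_pair(*pair, back)
        assert p1 == p2
        np.testing.assert_array_equal(m1, m2)

    def test_training_moves_predictions(self, tiny_checkpoint):
        """A trained checkpoint is not the initialization: predictions on a
        probe pair differ from the untrained model's."""
        from mirtarget.model import TargetModel

        untrained = TargetModel(tiny_checkpoint.model_config, seed=5)
        untrained.eval()
        pair = [("AGCUAGCUAGCUAGCUAGCUAG", "AGCU" * 12)]
        before = untrained.predict_batch(pair)[0]
        after = tiny_checkpoint.build_model().predict_batch(pair)[0]
        assert before != after
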
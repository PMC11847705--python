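"""Architecture contracts, losses, transfer-freeze protocol, training."""

import numpy as np
import pytest

from comet.comet_net import (EHREncoderConfig, EHROnlyNet, ModelData,
                             MultimodalNet, OmicsOnlyNet, PredictionSet,
                             bce_loss, grid_search, loss, mse_loss,
                             pretrain_ehr, train_multimodal,
                             transfer_and_freeze)
from comet.eval_harness import prepare_model_data
from comet.nn import GRU, Tensor


def toy_data(rng, n=12, L=4, d=3, P=5, binary=False):
    y = rng.standard_normal(n)
    if binary:
        y = (y > 0).astype(float)
    return ModelData(ehr=rng.standard_normal((n, L, d)),
                     mask=np.ones((n, L), bool),
                     omics=rng.standard_normal((n, P)),
                     y=y,
                     record_ids=[f"r{i}" for i in range(n)],
                     patient_ids=[f"p{i}" for i in range(n)])


class TestLosses:
    def test_mse_identity_and_hand_value(self):
        assert float(mse_loss(Tensor(np.array([1.0, 2.0])),
                              np.array([1.0, 2.0])).data) == 0.0
        # ((1-0)^2 + (2-0)^2) / 2 = 2.5
        assert float(mse_loss(Tensor(np.array([0.0, 0.0])),
                              np.array([1.0, 2.0])).data) == pytest.approx(2.5)

    def test_bce_at_half_is_ln2(self):
        v = float(bce_loss(Tensor(np.array([0.5])), np.array([1.0])).data)
        assert v == pytest.approx(np.log(2), abs=1e-9)

    def test_bce_clamps_extreme_predictions(self):
        v = float(bce_loss(Tensor(np.array([0.0])), np.array([1.0])).data)
        assert np.isfinite(v)

    def test_prediction_set_loss_wrapper(self):
        ps = PredictionSet(y_true=[1.0, 2.0], y_pred=[0.0, 0.0])
        assert loss(ps, "regression") == pytest.approx(2.5)
        with pytest.raises(ValueError):
            PredictionSet(y_true=[1.0], y_pred=[1.0, 2.0])


class TestForward:
    def test_combiner_unit_vector_masks_other_branches(self, rng):
        cfg = EHREncoderConfig(hidden_dim=6, seed=0)
        net = MultimodalNet(3, 5, cfg, "regression", rng)
        net.combiner.W.data = np.array([[1.0], [0.0], [0.0]])
        data = toy_data(rng)
        base = net.predict(data)
        perturbed = toy_data(np.random.default_rng(1))
        perturbed.ehr = data.ehr
        perturbed.mask = data.mask
        perturbed.y = data.y
        assert np.allclose(net.predict(perturbed), base)

    def test_no_bias_means_zero_branches_give_zero(self, rng):
        cfg = EHREncoderConfig(hidden_dim=4, seed=0)
        net = MultimodalNet(3, 5, cfg, "regression", rng)
        data = toy_data(rng, n=4)
        _, branch, _ = net.forward(data)
        manual = branch.data @ net.combiner.W.data
        assert np.allclose(net.predict(data), manual[:, 0])
        net.combiner.W.data[:] = 0.0  # zero mixing weights -> exactly zero
        assert np.allclose(net.predict(data), 0.0)

    def test_classification_zero_logit_gives_half(self, rng):
        cfg = EHREncoderConfig(hidden_dim=4, seed=0)
        net = MultimodalNet(3, 5, cfg, "classification", rng)
        net.combiner.W.data[:] = 0.0
        data = toy_data(rng, n=4, binary=True)
        assert np.allclose(net.predict(data), 0.5)

    def test_branch_separability_matches_single_branch_nets(self, rng):
        """Unit-vector combiner reproduces the standalone branch models."""
        cfg = EHREncoderConfig(hidden_dim=6, dropout=0.0, seed=0)
        net = MultimodalNet(3, 5, cfg, "regression", rng)
        data = toy_data(rng)
        ehr_net = EHROnlyNet(net.encoder, 6, "regression",
                             np.random.default_rng(9))
        ehr_net.head.load_state_dict(net.ehr_head.state_dict())
        om_net = OmicsOnlyNet(5, "regression", np.random.default_rng(9))
        om_net.head.load_state_dict(net.omics_head.state_dict())
        for j, single in ((0, ehr_net), (1, om_net)):
            net.combiner.W.data[:] = 0.0
            net.combiner.W.data[j, 0] = 1.0
            assert np.allclose(net.predict(data),
                               single.forward(data).data, atol=1e-12)


class TestTransfer:
    def make_pretrained(self, rng, cfg):
        enc = GRU(3, cfg.hidden_dim, cfg.n_layers, cfg.dropout, rng)
        return EHROnlyNet(enc, cfg.hidden_dim, "regression", rng)

    def test_encoder_copied_and_frozen_through_training(self, rng):
        cfg = EHREncoderConfig(hidden_dim=5, max_epochs=3, seed=0,
                               batch_size_omics=4)
        pre = self.make_pretrained(rng, cfg)
        net = MultimodalNet(3, 5, cfg, "regression",
                            np.random.default_rng(1))
        net = transfer_and_freeze(pre, net)
        before = {k: v.tobytes() for k, v in net.encoder.state_dict().items()}
        data = toy_data(rng)
        net, _ = train_multimodal(net, data, data, cfg, "regression")
        after = {k: v.tobytes() for k, v in net.encoder.state_dict().items()}
        assert before == after  # bitwise identical
        # heads did move
        assert not np.array_equal(net.combiner.W.data,
                                  np.zeros_like(net.combiner.W.data))

    def test_transfer_then_no_training_preserves_ehr_branch(self, rng):
        cfg = EHREncoderConfig(hidden_dim=5, dropout=0.0, seed=0)
        pre = self.make_pretrained(rng, cfg)
        net = transfer_and_freeze(pre, MultimodalNet(
            3, 5, cfg, "regression", np.random.default_rng(1)))
        data = toy_data(rng)
        net.combiner.W.data[:] = [[1.0], [0.0], [0.0]]
        assert np.allclose(net.predict(data), pre.forward(data).data)

    def test_mismatched_hidden_dim_raises(self, rng):
        pre = self.make_pretrained(rng, EHREncoderConfig(hidden_dim=5))
        fresh = MultimodalNet(3, 5, EHREncoderConfig(hidden_dim=7),
                              "regression", rng)
        with pytest.raises(ValueError, match="transfer mismatch"):
            transfer_and_freeze(pre, fresh)


class TestTraining:
    def test_pretrain_runs_on_single_patient(self, rng):
        cfg = EHREncoderConfig(hidden_dim=4, max_epochs=3, seed=0,
                               batch_size_pretrain=2)
        data = toy_data(rng, n=1)
        net, trace = pretrain_ehr(data, cfg, "regression")
        assert trace.stop_epoch <= cfg.max_epochs
        assert all(np.isfinite(v).all() for v in net.state_dict().values())

    def test_pretrain_deterministic_given_seed(self, rng):
        cfg = EHREncoderConfig(hidden_dim=4, max_epochs=3, seed=12,
                               batch_size_pretrain=4)
        data = toy_data(np.random.default_rng(3), n=10)
        n1, _ = pretrain_ehr(data, cfg, "regression")
        n2, _ = pretrain_ehr(data, cfg, "regression")
        for k, v in n1.state_dict().items():
            assert np.array_equal(v, n2.state_dict()[k])

    def test_pretraining_learns_signal(self, tiny_bundle, tiny_tables,
                                       fast_config):
        bundle, _ = tiny_bundle
        pre_table, _ = tiny_tables
        data = prepare_model_data(bundle.pretraining, table=pre_table,
                                  with_omics=False)
        fast_config.max_epochs = 15
        net, trace = pretrain_ehr(data, fast_config, "regression")
        pred = net.forward(data).data
        r = np.corrcoef(pred, data.y)[0, 1]
        assert r > 0

    def test_early_stopping_halts_on_flat_test_loss(self, rng, monkeypatch):
        cfg = EHREncoderConfig(hidden_dim=4, max_epochs=50, patience=5,
                               seed=0, batch_size_omics=4, learning_rate=0.0)
        net = MultimodalNet(3, 5, cfg, "regression", rng)
        data = toy_data(rng)
        net, trace = train_multimodal(net, data, data, cfg, "regression")
        # zero learning rate -> loss flat -> stop after patience epochs
        assert trace.stop_epoch == 1 + cfg.patience

    def test_snapshots_recorded_per_epoch(self, rng):
        cfg = EHREncoderConfig(hidden_dim=4, max_epochs=3, patience=10,
                               seed=0, batch_size_omics=4)
        net = MultimodalNet(3, 5, cfg, "regression", rng)
        data = toy_data(rng)
        net, trace = train_multimodal(net, data, data, cfg, "regression",
                                      snapshot_params=True)
        assert len(trace.snapshots) == trace.stop_epoch


def test_checkpoint_roundtrip(tmp_path, rng):
    from comet.comet_net import save_checkpoint, load_checkpoint
    cfg = EHREncoderConfig(hidden_dim=5, seed=0)
    net = MultimodalNet(3, 4, cfg, "regression", rng)
    net.encoder.freeze(True)
    save_checkpoint(net, cfg, tmp_path / "ckpt.npz", extra={"note": "x"})
    state, meta = load_checkpoint(tmp_path / "ckpt.npz")
    for k, v in net.state_dict().items():
        assert np.array_equal(state[k], v)
    assert meta["note"] == "x"
    assert meta["config"]["hidden_dim"] == 5
    assert all(meta["frozen"][k] for k in meta["frozen"]
               if k.startswith("encoder."))


class TestGridSearch:
    def test_single_point_grid_returned(self):
        groups = np.repeat(np.arange(6), 2)
        best, means = grid_search([{"lr": 1.0}],
                                  lambda p, tr, st, va: 0.5, groups)
        assert best == {"lr": 1.0}
        assert means == [0.5]

    def test_grouped_folds_never_split_a_patient(self):
        groups = np.repeat([f"p{i}" for i in range(9)], 2)
        seen = []

        def fit_eval(point, tr, st, va):
            seen.append((set(groups[np.concatenate([tr, st])]),
                         set(groups[va])))
            return 0.0

        grid_search([{"a": 1}], fit_eval, groups)
        for train_g, val_g in seen:
            assert not train_g & val_g

    def test_dominant_point_selected(self):
        groups = np.repeat([f"p{i}" for i in range(9)], 2)
        best, _ = grid_search(
            [{"v": 3.0}, {"v": 1.0}, {"v": 2.0}],
            lambda p, tr, st, va: p["v"], groups)
        assert best == {"v": 1.0}
        best, _ = grid_search(
            [{"v": 3.0}, {"v": 1.0}], lambda p, tr, st, va: p["v"],
            groups, maximize=True)
        assert best == {"v": 3.0}

    def test_tie_keeps_first_grid_point(self):
        groups = np.repeat([f"p{i}" for i in range(9)], 2)
        best, _ = grid_search([{"id": "first"}, {"id": "second"}],
                              lambda p, tr, st, va: 1.0, groups)
        assert best == {"id": "first"}
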
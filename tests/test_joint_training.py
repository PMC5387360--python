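"""Losses, masking, training loop contracts and the three-stage protocol."""

import numpy as np
import pytest

from scmethyl import joint_training as jt
from scmethyl.autodiff import Tensor
from scmethyl.cpg_net import CpgNetConfig
from scmethyl.data_io import SiteDataset, make_split
from scmethyl.dna_net import DnaNetConfig
from scmethyl.nn import Param

TINY_DNA = DnaNetConfig(n_conv_pool_pairs=1, filters_per_layer=[4],
                        filter_lengths=[3], pool_size=2, fc_units=5)
TINY_CPG = CpgNetConfig(embed_units=5, hidden_units=4)


def make_pred(y_hat, y, o):
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    o = np.atleast_2d(np.asarray(o, dtype=float))
    sites = [("1", 10 * (i + 1)) for i in range(y.shape[0])]
    return jt.PredictionSet(sites, y_hat, y, o)


def random_dataset(rng, N=40, T=3, L_win=17, K=2):
    return SiteDataset(
        sites=[("1" if i < N // 2 else "2", 100 + 7 * i) for i in range(N)],
        windows=(rng.random((N, L_win, 4)) < 0.25).astype(float),
        contexts=rng.random((N, T, 4 * K)),
        y=(rng.random((N, T)) < 0.5).astype(float),
        o=(rng.random((N, T)) < 0.7).astype(float),
        cell_ids=[f"c{t}" for t in range(T)],
        L_win=L_win, K=K, max_dist=100.0)


class TestNllLoss:
    def test_single_observed_site(self):
        assert np.isclose(jt.nll_loss(make_pred(0.5, 1, 1)), -np.log(0.5))

    def test_fully_masked_is_zero(self):
        assert jt.nll_loss(make_pred([[0.9, 0.1]], [[1, 0]], [[0, 0]])) == 0.0

    def test_two_site_value(self):
        loss = jt.nll_loss(make_pred([[0.9, 0.1]], [[1, 0]], [[1, 1]]))
        assert np.isclose(loss, -2 * np.log(0.9))

    def test_clipping_keeps_loss_finite(self):
        assert np.isfinite(jt.nll_loss(make_pred([[0.0, 1.0]], [[1, 0]],
                                                 [[1, 1]])))


class TestTotalLoss:
    def test_lambda_zero_equals_nll(self):
        pred = make_pred([[0.7]], [[1]], [[1]])
        params = {"w": Param(np.array([2.0]), "w")}
        assert jt.total_loss(pred, params, 0.0) == jt.nll_loss(pred)

    def test_squared_norm_penalty(self):
        pred = make_pred([[0.5]], [[1]], [[0]])  # masked: NLL term 0
        params = {"w": Param(np.array([2.0]), "w")}
        assert np.isclose(jt.total_loss(pred, params, 1.0), 4.0)

    def test_biases_excluded(self):
        pred = make_pred([[0.5]], [[1]], [[0]])
        params = {"w/b": Param(np.array([3.0]), "w/b", is_bias=True)}
        assert jt.total_loss(pred, params, 1.0) == 0.0

    def test_unsquared_norm_option(self):
        pred = make_pred([[0.5]], [[1]], [[0]])
        params = {"w": Param(np.array([3.0, 4.0]), "w")}
        assert np.isclose(jt.total_loss(pred, params, 1.0, l2_squared=False),
                          5.0)


class TestJointForward:
    def test_zero_head_weights_give_half(self, rng):
        model = jt.JointModel(rng, __import__("scmethyl.dna_net", fromlist=["DnaNet"]
                                              ).DnaNet(rng, TINY_DNA, 17),
                              __import__("scmethyl.cpg_net", fromlist=["CpgNet"]
                                         ).CpgNet(rng, TINY_CPG, 8),
                              n_cells=3, joint_units=6)
        model.head.W.data[:] = 0.0
        model.head.b.data[:] = 0.0
        w = Tensor(np.zeros((2, 17, 4)))
        c = Tensor(np.zeros((2, 4, 8)))
        out = model.forward(w, c).data
        assert out.shape == (2, 3)
        assert np.allclose(out, 0.5)


class TestMaskingInvariance:
    def test_loss_and_gradients_ignore_unobserved_labels(self, rng):
        data = random_dataset(rng)
        model = jt.DnaModel(rng, TINY_DNA, data.L_win, data.n_cells)

        def loss_and_grads(y):
            for p in model.params().values():
                p.zero_grad()
            y_hat = model.forward(Tensor(data.windows))
            loss = jt._nll_t(y_hat, y, data.o)
            loss.backward()
            return float(loss.data), {n: p.grad.copy()
                                      for n, p in model.params().items()}

        l0, g0 = loss_and_grads(data.y)
        perturbed = data.y.copy()
        perturbed[data.o == 0] = 1.0 - perturbed[data.o == 0]
        l1, g1 = loss_and_grads(perturbed)
        assert l0 == l1
        for n in g0:
            assert np.array_equal(g0[n], g1[n])


class TestTrain:
    def _split_sets(self, data):
        split = make_split({c for c, _ in data.sites}, train={"1"}, test={"2"})
        cfg = jt.TrainConfig(seed=0, batch_size=8, max_epochs=30,
                             early_stop_patience_epochs=10)
        return jt.split_train_val(data, split, cfg), cfg

    def test_empty_training_set_rejected(self, rng):
        data = random_dataset(rng)
        model = jt.DnaModel(rng, TINY_DNA, data.L_win, data.n_cells)
        with pytest.raises(ValueError):
            jt.train(model, data.subset(np.array([], dtype=np.int64)),
                     data, jt.TrainConfig())

    def test_constant_val_loss_stops_after_patience(self, rng, monkeypatch):
        data = random_dataset(rng)
        (tr, va), cfg = self._split_sets(data)
        cfg = jt.TrainConfig(seed=0, batch_size=8, max_epochs=50,
                             early_stop_patience_epochs=4)
        monkeypatch.setattr(jt, "evaluate_loss", lambda *a, **k: 1.0)
        model = jt.DnaModel(rng, TINY_DNA, data.L_win, data.n_cells)
        log = jt.train(model, tr, va, cfg)
        assert len(log.epochs) == 1 + cfg.early_stop_patience_epochs

    def test_improving_val_loss_runs_all_epochs(self, rng, monkeypatch):
        data = random_dataset(rng)
        (tr, va), cfg = self._split_sets(data)
        cfg = jt.TrainConfig(seed=0, batch_size=8, max_epochs=12,
                             early_stop_patience_epochs=3)
        vals = iter(range(100, 0, -1))
        monkeypatch.setattr(jt, "evaluate_loss",
                            lambda *a, **k: float(next(vals)))
        model = jt.DnaModel(rng, TINY_DNA, data.L_win, data.n_cells)
        log = jt.train(model, tr, va, cfg)
        assert len(log.epochs) == 12

    def test_training_reduces_loss_on_separable_data(self, rng):
        # labels determined by a single window position: learnable signal
        data = random_dataset(rng, N=200)
        data.y[:] = data.windows[:, 8, 0:1]  # label = "A at center"
        data.o[:] = 1.0
        (splits, cfg) = self._split_sets(data)
        tr, va = splits
        model = jt.DnaModel(rng, TINY_DNA, data.L_win, data.n_cells)
        cfg = jt.TrainConfig(seed=0, batch_size=16, max_epochs=40,
                             learning_rate=3e-3,
                             early_stop_patience_epochs=40)
        log = jt.train(model, tr, va, cfg)
        assert log.epochs[-1]["train_loss"] < 0.5 * log.epochs[0]["train_loss"]

    def test_seeded_determinism(self, rng):
        data = random_dataset(rng)
        split = make_split({c for c, _ in data.sites}, train={"1"}, test={"2"})
        cfg = jt.TrainConfig(seed=5, batch_size=8, max_epochs=5,
                             early_stop_patience_epochs=5)
        tr, va = jt.split_train_val(data, split, cfg)
        states = []
        for _ in range(2):
            model = jt.DnaModel(np.random.default_rng(cfg.seed), TINY_DNA,
                                data.L_win, data.n_cells)
            jt.train(model, tr, va, cfg)
            states.append(model.state_dict())
        for name in states[0]:
            assert np.array_equal(states[0][name], states[1][name])


class TestTrainProtocol:
    def test_freeze_contract_and_standalone_modules(self, rng):
        data = random_dataset(rng, N=60)
        split = make_split({c for c, _ in data.sites}, train={"1"}, test={"2"})
        cfg = jt.TrainConfig(seed=0, batch_size=16, max_epochs=3,
                             early_stop_patience_epochs=3)
        models, logs = jt.train_protocol(data, split, cfg, TINY_DNA, TINY_CPG,
                                         joint_units=6)
        # frozen DNA/CpG tensors bitwise identical to their pre-trained values
        joint = models["joint"]
        for name, p in models["dna"].dna.params().items():
            assert np.array_equal(p.data, joint.dna.params()[name].data)
        for name, p in models["cpg"].cpg.params().items():
            assert np.array_equal(p.data, joint.cpg.params()[name].data)
        # stage-3 log lists only joint parameter groups as trainable
        assert logs["joint"].trainable_groups == ["joint"]
        # pre-trained models usable standalone
        for kind in ("dna", "cpg"):
            y_hat = models[kind].predict(data)
            assert y_hat.shape == (data.n_sites, data.n_cells)
            assert ((y_hat >= 0) & (y_hat <= 1)).all()


class TestPersistence:
    def test_save_load_roundtrip(self, rng, tmp_path):
        data = random_dataset(rng)
        model = jt.DnaModel(rng, TINY_DNA, data.L_win, data.n_cells)
        path = tmp_path / "model.npy"
        jt.save_model(model, path, meta={"max_dist": 123.0})
        loaded, meta = jt.load_model(path)
        assert meta["max_dist"] == 123.0
        assert np.array_equal(loaded.predict(data), model.predict(data))

    def test_saved_bytes_deterministic(self, rng, tmp_path):
        data = random_dataset(rng)
        paths = []
        for i in range(2):
            model = jt.DnaModel(np.random.default_rng(3), TINY_DNA,
                                data.L_win, data.n_cells)
            p = tmp_path / f"m{i}.npy"
            jt.save_model(model, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
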
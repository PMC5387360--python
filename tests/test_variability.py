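"""Window mean/variance targets, MSE objective, fine-tuning, classification."""

import copy

import numpy as np
import pytest

from scmethyl import joint_training as jt
from scmethyl import variability as vb
from scmethyl.data_io import MethylationProfile
from scmethyl.dna_net import DnaNet, DnaNetConfig
from scmethyl.nn import Param


def profile_from_dict(cell_id, sites):
    prof = MethylationProfile(cell_id=cell_id)
    by_chrom = {}
    for (chrom, pos), state in sites.items():
        by_chrom.setdefault(chrom, []).append((pos, state))
    for chrom, rows in by_chrom.items():
        rows.sort()
        prof.positions[chrom] = np.array([p for p, _ in rows], dtype=np.int64)
        prof.states[chrom] = np.array([s for _, s in rows], dtype=np.uint8)
    return prof


class TestWindowTargets:
    def test_two_cell_closed_form(self):
        cells = [profile_from_dict("a", {("1", 100): 0, ("1", 150): 0}),
                 profile_from_dict("b", {("1", 100): 1, ("1", 150): 1})]
        ws = vb.window_targets(cells, "1", 120, scales=(200,))
        assert ws.m[0] == 0.5 and ws.v[0] == 0.25

    def test_identical_cells_zero_variance(self):
        cells = [profile_from_dict(c, {("1", 100): 1, ("1", 110): 0,
                                       ("1", 120): 0, ("1", 130): 0,
                                       ("1", 140): 0, ("1", 150): 0,
                                       ("1", 160): 0, ("1", 170): 0,
                                       ("1", 180): 0, ("1", 190): 1})
                 for c in "abc"]
        ws = vb.window_targets(cells, "1", 145, scales=(200,))
        assert ws.v[0] == pytest.approx(0.0, abs=1e-12)
        assert np.isclose(ws.m[0], 0.2)

    def test_three_cell_mixed_rates(self):
        # per-cell means 0.2, 0.4, 0.9 -> m = 0.5, v = 0.08667
        def cell(cid, k):
            states = {("1", 100 + 10 * i): int(i < k) for i in range(10)}
            return profile_from_dict(cid, states)
        cells = [cell("a", 2), cell("b", 4), cell("c", 9)]
        ws = vb.window_targets(cells, "1", 145, scales=(500,))
        assert np.isclose(ws.m[0], 0.5)
        assert np.isclose(ws.v[0], (0.09 + 0.01 + 0.16) / 3)

    def test_cell_without_observations_excluded(self):
        cells = [profile_from_dict("a", {("1", 100): 1}),
                 profile_from_dict("b", {("1", 110): 0}),
                 profile_from_dict("c", {("2", 100): 1})]
        ws = vb.window_targets(cells, "1", 105, scales=(100,))
        # cell c excluded; remaining means {1, 0}
        assert ws.m[0] == 0.5 and ws.v[0] == 0.25
        assert np.isnan(ws.m_per_cell[0, 2])

    def test_fewer_than_two_cells_undefined(self):
        cells = [profile_from_dict("a", {("1", 100): 1}),
                 profile_from_dict("b", {("2", 100): 0})]
        ws = vb.window_targets(cells, "1", 100, scales=(50,))
        assert np.isnan(ws.m[0]) and np.isnan(ws.v[0])

    def test_matches_bruteforce_on_random_profiles(self, rng):
        for _ in range(30):
            cells = []
            for t in range(4):
                n = rng.integers(3, 30)
                pos = np.sort(rng.choice(np.arange(1, 3000), n, replace=False))
                cells.append(profile_from_dict(
                    f"c{t}", {("1", int(p)): int(rng.random() < 0.5)
                              for p in pos}))
            target = int(rng.integers(1, 3000))
            s = int(rng.choice([200, 500, 1000]))
            ws = vb.window_targets(cells, "1", target, scales=(s,))
            means = []
            for prof in cells:
                inside = [st for p, st in zip(prof.positions["1"],
                                              prof.states["1"])
                          if target - s // 2 <= p <= target + s // 2]
                if inside:
                    means.append(np.mean(inside))
            if len(means) >= 2:
                assert np.isclose(ws.m[0], np.mean(means))
                assert np.isclose(ws.v[0], np.mean(
                    (np.array(means) - np.mean(means)) ** 2))
            else:
                assert np.isnan(ws.m[0])

    def test_variance_bounded_by_quarter(self, rng):
        for _ in range(20):
            cells = [profile_from_dict(
                f"c{t}", {("1", int(p)): int(rng.random() < 0.5)
                          for p in rng.choice(np.arange(1, 500), 10,
                                              replace=False)})
                for t in range(3)]
            ws = vb.window_targets(cells, "1", 250, scales=(300,))
            if not np.isnan(ws.v[0]):
                assert 0.0 <= ws.v[0] <= 0.25
                assert 0.0 <= ws.m[0] <= 1.0


class TestMseLoss:
    def test_perfect_predictions(self):
        m = np.array([[0.3]]); v = np.array([[0.1]])
        mask = np.ones((1, 1), dtype=bool)
        assert vb.mse_loss(m, v, m, v, mask) == 0.0

    def test_single_site_value(self):
        m = np.array([[0.3]]); v = np.array([[0.1]])
        mh = np.array([[0.4]]); vh = np.array([[0.3]])
        mask = np.ones((1, 1), dtype=bool)
        assert np.isclose(vb.mse_loss(mh, vh, m, v, mask), 0.01 + 0.04)

    def test_undefined_targets_skipped(self):
        m = np.array([[np.nan, 0.5]]); v = np.array([[np.nan, 0.0]])
        mh = np.zeros((1, 2)); vh = np.zeros((1, 2))
        mask = np.array([[False, True]])
        assert np.isclose(vb.mse_loss(mh, vh, m, v, mask), 0.25)

    def test_l2_term_added(self):
        m = np.zeros((1, 1)); v = np.zeros((1, 1))
        mask = np.ones((1, 1), dtype=bool)
        params = {"w": Param(np.array([2.0]), "w")}
        assert np.isclose(vb.mse_loss(m, v, m, v, mask, l2_lambda=0.5,
                                      params=params), 2.0)


class TestFinetune:
    def _setup(self, rng):
        cfg = DnaNetConfig(n_conv_pool_pairs=1, filters_per_layer=[3],
                           filter_lengths=[3], pool_size=2, fc_units=4)
        dna = DnaNet(rng, cfg, L_win=21)
        windows = (rng.random((30, 21, 4)) < 0.25).astype(float)
        m = rng.random((30, 2))
        v = rng.random((30, 2)) * 0.25
        mask = np.ones((30, 2), dtype=bool)
        return dna, windows, m, v, mask

    def test_first_conv_layer_frozen_bitwise(self, rng):
        dna, windows, m, v, mask = self._setup(rng)
        w_before = dna.conv_layers[0].W.data.copy()
        b_before = dna.conv_layers[0].b.data.copy()
        fc_before = dna.fc.W.data.copy()
        cfg = jt.TrainConfig(seed=0, batch_size=10, max_epochs=4,
                             learning_rate=1e-2, early_stop_patience_epochs=4)
        net = vb.finetune_varnet(dna, windows, m, v, mask, cfg,
                                 scales=(1000, 2000))
        assert np.array_equal(net.dna.conv_layers[0].W.data, w_before)
        assert np.array_equal(net.dna.conv_layers[0].b.data, b_before)
        assert not np.array_equal(net.dna.fc.W.data, fc_before)

    def test_head_width_is_twice_scale_count(self, rng):
        dna, windows, m, v, mask = self._setup(rng)
        cfg = jt.TrainConfig(seed=0, batch_size=10, max_epochs=1,
                             early_stop_patience_epochs=1)
        net = vb.finetune_varnet(dna, windows, m, v, mask, cfg,
                                 scales=(1000, 2000))
        assert net.head.W.data.shape[1] == 4
        mh, vh = net.predict(windows)
        assert mh.shape == (30, 2) and vh.shape == (30, 2)
        assert ((mh > 0) & (mh < 1)).all() and ((vh > 0) & (vh < 1)).all()

    def test_source_module_untouched(self, rng):
        dna, windows, m, v, mask = self._setup(rng)
        state = {k: a.copy() for k, a in dna.state_dict().items()}
        cfg = jt.TrainConfig(seed=0, batch_size=10, max_epochs=2,
                             early_stop_patience_epochs=2)
        vb.finetune_varnet(dna, windows, m, v, mask, cfg,
                           scales=(1000, 2000))
        for k, a in dna.state_dict().items():
            assert np.array_equal(a, state[k])


class TestVarianceMeanClassification:
    def test_variance_associated_filter(self, rng):
        v_hat = rng.random((30, 1))
        m_hat = rng.random((30, 1))
        act = v_hat.copy()  # tracks variance exactly
        r_v, r_m, r_d, labels = vb.variance_mean_classification(act, m_hat,
                                                                v_hat)
        assert r_v[0, 0] == pytest.approx(1.0)
        assert labels[0][0] == "variance"

    def test_mean_associated_filter(self, rng):
        v_hat = rng.random((30, 1))
        m_hat = rng.random((30, 1))
        act = m_hat.copy()
        _, r_m, r_d, labels = vb.variance_mean_classification(act, m_hat,
                                                              v_hat)
        assert r_m[0, 0] == pytest.approx(1.0)
        assert labels[0][0] == "mean"

    def test_balanced_association_is_neither(self):
        base = np.linspace(0, 1, 30)[:, None]
        r_v, r_m, r_d, labels = vb.variance_mean_classification(
            base, base.copy(), base.copy())
        assert r_d[0, 0] == pytest.approx(0.0)
        assert labels[0][0] == "neither"

    def test_degenerate_activity_undetermined(self, rng):
        act = np.full((30, 1), 0.5)
        labels = vb.variance_mean_classification(act, rng.random((30, 1)),
                                                 rng.random((30, 1)))[3]
        assert labels[0][0] == "undetermined"
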
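"""Architecture contracts of the three classifiers."""

import numpy as np
import pytest
from sklearn.base import clone

from methynet import models
from methynet.models import (DnaCnnClassifier, JointMethylationClassifier,
                             NeighborGruClassifier, binarize)


def small_dna(**kw):
    p = dict(window_radius=30, conv1_filters=6, conv2_filters=4, fc_units=8,
             max_epochs=2, validation_fraction=0.0, random_state=0)
    p.update(kw)
    return DnaCnnClassifier(**p)


def small_meth(**kw):
    p = dict(k_neighbors=5, td_units=4, gru1_units=3, gru2_units=4,
             max_epochs=2, validation_fraction=0.0, random_state=0)
    p.update(kw)
    return NeighborGruClassifier(**p)


def small_joint(**kw):
    p = dict(window_radius=30, conv1_filters=6, conv2_filters=4, fc_units=8,
             k_neighbors=5, td_units=4, gru1_units=3, gru2_units=4,
             joint_units=6, max_epochs=2, validation_fraction=0.0,
             random_state=0)
    p.update(kw)
    return JointMethylationClassifier(**p)


def rand_inputs(rng, n, model):
    L = model.seq_length if hasattr(model, "seq_length") else None
    seq = None if L is None else rng.integers(0, 2, (n, L, 4)).astype(np.float32)
    nbr = rng.random((n, 4 * getattr(model, "k_neighbors", 25))).astype(np.float32)
    return seq, nbr


class TestArchitectureFacts:
    """Dimensional facts of the default (full-scale) architectures."""

    def test_first_layer_filter_tensor_shape(self):
        m = models.build_dna_model()
        assert m.first_layer_filters_.shape == (128, 11, 4)

    def test_dna_embedding_is_256(self, rng):
        m = models.build_dna_model()
        x = rng.integers(0, 2, (2, 1001, 4)).astype(np.float32)
        assert m.embed(x).shape == (2, 256)

    def test_meth_embedding_is_512(self, rng):
        m = models.build_meth_model()
        assert m.spec.embedding_dim == 512
        x = rng.random((2, 100)).astype(np.float32)
        assert m.embed(x).shape == (2, 512)

    def test_joint_concat_is_768(self):
        m = models.build_joint_model()
        assert m.input_dim == 768

    def test_parameter_counts_match_closed_forms(self):
        # DNA: conv(11x4->128), conv(3x128->256), dense(122*256 -> 256), head
        dna = models.build_dna_model()
        l1 = 1001 - 11 + 1            # 991
        p1 = l1 // 4                  # 247
        l2 = p1 - 3 + 1               # 245
        p2 = l2 // 2                  # 122
        expect = ((11 * 4) * 128 + 128) + ((3 * 128) * 256 + 256) \
            + (p2 * 256) * 256 + 256 + (256 + 1)
        assert dna.n_parameters_ == expect

        # Meth: td dense(2->32), BiGRU(32->128), BiGRU(256->256), head
        meth = models.build_meth_model()
        gru = lambda i, h: 2 * (i * 3 * h + h * 3 * h + 6 * h)  # both directions
        expect = (2 * 32 + 32) + gru(32, 128) + gru(256, 256) + (512 + 1)
        assert meth.n_parameters_ == expect

        # Joint: both bodies + dense(768->512), dense(512->512), dense(512->1)
        joint = models.build_joint_model()
        dna_body = ((11 * 4) * 128 + 128) + ((3 * 128) * 256 + 256) \
            + (p2 * 256) * 256 + 256
        meth_body = (2 * 32 + 32) + gru(32, 128) + gru(256, 256)
        head = (768 * 512 + 512) + (512 * 512 + 512) + (512 + 1)
        assert joint.n_parameters_ == dna_body + meth_body + head


class TestForwardContracts:
    def test_all_zero_window_gives_probability_in_open_interval(self, rng):
        m = small_dna().initialize()
        p = m.predict_probability(np.zeros((1, 61, 4), dtype=np.float32))
        assert 0.0 < p[0] < 1.0

    def test_all_pad_neighbor_input_valid(self):
        m = small_meth().initialize()
        x = np.concatenate([np.full(10, 0.5), np.full(10, 1.0)])[None, :]
        p = m.predict_probability(x.astype(np.float32))
        assert 0.0 < p[0] < 1.0

    def test_probabilities_bounded_for_wild_inputs(self, rng):
        m = small_meth().initialize()
        x = (rng.standard_normal((8, 20)) * 1e3).astype(np.float32)
        p = m.predict_probability(x)
        assert ((p >= 0) & (p <= 1)).all()

    def test_reversed_timesteps_change_embedding(self, rng):
        m = small_meth().initialize()
        x = rng.random((1, 20)).astype(np.float32)
        k = 5
        rev = np.concatenate([x[:, :2 * k][:, ::-1], x[:, 2 * k:][:, ::-1]],
                             axis=1)
        assert not np.allclose(m.embed(x), m.embed(rev), atol=1e-6)

    def test_joint_composes_from_branch_embeddings(self, rng):
        m = small_joint().initialize()
        seq, nbr = rand_inputs(rng, 3, m)
        full = m.predict_probability((seq, nbr))
        e = m.embed((seq, nbr))
        manual = 1 / (1 + np.exp(-m.net_.head.forward(e).ravel()))
        np.testing.assert_allclose(full, manual, rtol=1e-5)

    def test_zero_head_outputs_exactly_half(self, rng):
        m = small_joint().initialize()
        for layer in m.net_.head.param_layers():
            for k in layer.params:
                layer.params[k][...] = 0.0
        seq, nbr = rand_inputs(rng, 4, m)
        np.testing.assert_array_equal(m.predict_probability((seq, nbr)), 0.5)

    def test_wrong_input_shape_rejected(self, rng):
        with pytest.raises(ValueError, match="expected windows"):
            small_dna().initialize().predict_probability(
                rng.random((2, 50, 4)).astype(np.float32))
        with pytest.raises(ValueError, match="neighbor vectors"):
            small_meth().initialize().predict_probability(
                rng.random((2, 21)).astype(np.float32))


class TestPredict:
    def test_binarization_boundary_is_strict(self):
        assert binarize([0.5, 0.5000001, 0.4999999]).tolist() == [0, 1, 0]

    def test_predict_proba_shape_and_sum(self, rng):
        m = small_meth().initialize()
        x = rng.random((6, 20)).astype(np.float32)
        p = m.predict_proba(x)
        assert p.shape == (6, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)

    def test_batched_equals_single(self, rng):
        m = small_dna().initialize()
        x = rng.integers(0, 2, (9, 61, 4)).astype(np.float32)
        full = m.predict_probability(x)
        single = np.concatenate([m.predict_probability(x[i:i + 1])
                                 for i in range(9)])
        np.testing.assert_allclose(full, single, rtol=1e-5)


class TestFit:
    def _toy(self, rng, n=64):
        nbr = rng.random((n, 20)).astype(np.float32)
        y = (nbr[:, :10].mean(axis=1) > 0.5).astype(float)
        return nbr, y

    def test_separable_meth_problem_learned(self, rng):
        nbr, y = self._toy(rng, 256)
        m = small_meth(max_epochs=30, learning_rate=0.01,
                       validation_fraction=0.0, l1=0.0, l2=0.0)
        m.fit(nbr, y)
        acc = (m.predict(nbr) == y).mean()
        assert acc > 0.9

    def test_same_seed_reproducible(self, rng):
        nbr, y = self._toy(rng)
        hist = []
        for _ in range(2):
            m = small_meth(max_epochs=3)
            m.fit(nbr, y)
            hist.append(m.history_.epochs[-1]["train_loss"])
        assert hist[0] == hist[1]

    def test_single_class_warns_but_fits(self, rng):
        nbr, _ = self._toy(rng)
        with pytest.warns(UserWarning, match="single class"):
            small_meth().fit(nbr, np.zeros(len(nbr)))

    def test_non_binary_labels_rejected(self, rng):
        nbr, _ = self._toy(rng)
        with pytest.raises(ValueError, match="binary"):
            small_meth().fit(nbr, np.full(len(nbr), 0.3))

    def test_history_recorded_per_epoch(self, rng):
        nbr, y = self._toy(rng)
        m = small_meth(max_epochs=4)
        m.fit(nbr, y)
        frame = m.history_.to_frame()
        assert list(frame["epoch"]) == [0, 1, 2, 3]
        assert "train_loss" in frame


class TestSklearnInterface:
    def test_get_params_set_params_clone(self):
        m = small_dna(learning_rate=0.5)
        c = clone(m)
        assert c.get_params()["learning_rate"] == 0.5
        c.set_params(fc_units=12)
        assert c.fc_units == 12

    def test_warm_start_copies_branch_weights(self, rng):
        dna = small_dna().initialize()
        meth = small_meth().initialize()
        joint = small_joint(warm_start_models=(dna, meth)).initialize()
        np.testing.assert_array_equal(
            joint.net_.dna.layers[0].params["W"],
            dna.net_.body.layers[0].params["W"])

    def test_first_layer_filters_require_dna_or_joint(self):
        with pytest.raises(ValueError, match="DNA/joint"):
            models.get_first_layer_filters(small_meth().initialize())


class TestSerialization:
    def test_save_load_round_trip_bit_exact(self, rng, tmp_path):
        from methynet.encode import EncodingSpec
        m = small_dna().initialize()
        m.set_encoding(EncodingSpec(window_radius=30, k_neighbors=5, d_max=77))
        path = tmp_path / "m.npz"
        models.save_model(m, path)
        back = models.load_model(path)
        np.testing.assert_array_equal(back.first_layer_filters_,
                                      m.first_layer_filters_)
        assert back.encoding_spec_.d_max == 77
        x = rng.integers(0, 2, (3, 61, 4)).astype(np.float32)
        np.testing.assert_allclose(back.predict_probability(x),
                                   m.predict_probability(x), rtol=1e-6)
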
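"""Filter activations, window selection, PWMs, activity, effect, PCA."""

import numpy as np
import pytest

from methynet import motifs as mo
from methynet.models import DnaCnnClassifier


@pytest.fixture
def dna_model():
    return DnaCnnClassifier(window_radius=30, conv1_filters=8,
                            conv2_filters=4, fc_units=8,
                            random_state=3).initialize()


def one_hot(seq):
    """A,T,G,C channel order, N -> zero row."""
    lut = {"A": 0, "T": 1, "G": 2, "C": 3}
    out = np.zeros((len(seq), 4), dtype=np.float32)
    for i, b in enumerate(seq):
        if b in lut:
            out[i, lut[b]] = 1.0
    return out


def brute_force_select(acts, windows, fraction=0.5, width=11):
    """Independent re-scan of the selection rule."""
    alphabet = "ATGCN"
    out = []
    for f in range(acts.shape[2]):
        bar = fraction * acts[:, :, f].max()
        kmers = []
        for w in range(acts.shape[0]):
            p = int(acts[w, :, f].argmax())
            if acts[w, p, f] > bar:
                sub = windows[w, p : p + width]
                kmer = "".join(
                    alphabet[4] if sub[i].sum() == 0 else alphabet[int(sub[i].argmax())]
                    for i in range(width))
                if "N" not in kmer:
                    kmers.append(kmer)
        out.append(kmers)
    return out


class TestFilterActivations:
    def test_valid_positions_only(self, dna_model, rng):
        w = rng.integers(0, 2, (3, 61, 4)).astype(np.float32)
        acts = mo.filter_activations(dna_model, w)
        assert acts.shape == (3, 61 - 11 + 1, 8)

    def test_all_zero_window_activates_relu_of_bias(self, dna_model):
        conv = dna_model.net_.body.layers[0]
        conv.params["b"][...] = np.linspace(-0.5, 0.5, 8)
        acts = mo.filter_activations(dna_model, np.zeros((1, 61, 4), np.float32))
        expect = np.maximum(conv.params["b"], 0.0)
        np.testing.assert_allclose(acts[0], np.tile(expect, (acts.shape[1], 1)),
                                   atol=1e-7)

    def test_activation_is_clamped_dot_product(self, dna_model, rng):
        w = rng.integers(0, 2, (1, 61, 4)).astype(np.float32)
        acts = mo.filter_activations(dna_model, w)
        filt = dna_model.first_layer_filters_          # (8, 11, 4)
        conv = dna_model.net_.body.layers[0]
        for p in (0, 17, 50):
            manual = (w[0, p : p + 11] * filt[2]).sum() + conv.params["b"][2]
            assert acts[0, p, 2] == pytest.approx(max(manual, 0.0), abs=1e-5)

    def test_meth_model_rejected(self):
        from methynet.models import NeighborGruClassifier
        m = NeighborGruClassifier(k_neighbors=5, td_units=2, gru1_units=2,
                                  gru2_units=2).initialize()
        with pytest.raises(ValueError, match="DNA/joint"):
            mo.filter_activations(m, np.zeros((1, 61, 4), np.float32))


class TestSelectWindows:
    def test_planted_filter_selects_exactly_matching_sequences(self, rng):
        """A hand-built filter that scores TATATATATAT picks exactly the
        windows containing it."""
        model = DnaCnnClassifier(window_radius=30, conv1_filters=2,
                                 conv2_filters=2, fc_units=4,
                                 random_state=0).initialize()
        conv = model.net_.body.layers[0]
        target = "TATATATATAT"
        # +1 on the consensus base, -1 elsewhere: activation = matches -
        # mismatches, so only near-exact occurrences clear the 50% bar
        W = np.zeros((11, 4, 2), dtype=np.float32)
        W[:, :, 0] = -1.0
        for i, b in enumerate(target):
            W[i, "ATGC".index(b), 0] = 1.0
        conv.params["W"][...] = W.reshape(44, 2)
        conv.params["b"][...] = 0.0

        bases = np.array(list("ACGT"))
        def rand_seq(n):
            return "".join(bases[rng.integers(0, 4, n)])
        with_motif = [rand_seq(20) + target + rand_seq(30) for _ in range(5)]
        without = [rand_seq(61).replace("TATATA", "AAAAAA") for _ in range(5)]
        windows = np.stack([one_hot(s) for s in with_motif + without])
        acts = mo.filter_activations(model, windows)
        sel = mo.select_windows(acts, windows)
        assert sorted(sel[0]) == [target] * 5

    def test_zero_activation_filter_selects_nothing(self, dna_model):
        acts = np.zeros((4, 51, 8), dtype=np.float32)
        windows = np.zeros((4, 61, 4), dtype=np.float32)
        sel = mo.select_windows(acts, windows)
        assert all(len(s) == 0 for s in sel)

    def test_matches_brute_force_rescan(self, dna_model, rng):
        windows = rng.integers(0, 2, (20, 61, 4)).astype(np.float32)
        acts = mo.filter_activations(dna_model, windows)
        got = mo.select_windows(acts, windows)
        want = brute_force_select(np.asarray(acts), windows)
        assert got == want

    def test_fraction_out_of_range_rejected(self, dna_model):
        acts = np.zeros((1, 51, 8), dtype=np.float32)
        with pytest.raises(ValueError, match="fraction"):
            mo.select_windows(acts, np.zeros((1, 61, 4)), fraction=1.5)


class TestBuildPwm:
    def test_identical_kmers_no_pseudocount_max_information(self):
        pwm, ic = mo.build_pwm(["ACGTACGTACG"] * 10, pseudocount=0.0)
        assert ic == pytest.approx(22.0)
        assert set(np.unique(pwm)) == {0.0, 1.0}

    def test_empty_selection_uniform_zero_information(self):
        pwm, ic = mo.build_pwm([], pseudocount=0.5)
        np.testing.assert_allclose(pwm, 0.25)
        assert ic == 0.0

    def test_pseudocount_formula(self):
        # 1xA + 1xT at each position, n=2: P = (c + 0.5) / (n + 2)
        pwm, _ = mo.build_pwm(["A" * 11, "T" * 11], pseudocount=0.5)
        np.testing.assert_allclose(pwm[:, 0], 1.5 / 4)   # A column
        np.testing.assert_allclose(pwm[:, 3], 1.5 / 4)   # T column
        np.testing.assert_allclose(pwm[:, 1], 0.5 / 4)   # C column

    def test_permutation_invariance(self, rng):
        kmers = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 11)])
                 for _ in range(30)]
        a, _ = mo.build_pwm(kmers)
        perm = list(kmers)
        rng.shuffle(perm)
        b, _ = mo.build_pwm(perm)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad", ["ACGT", "ACGTACGTACN"])
    def test_invalid_subsequences_rejected(self, bad):
        with pytest.raises(ValueError):
            mo.build_pwm([bad])

    def test_rows_sum_to_one(self, rng):
        kmers = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 11)])
                 for _ in range(7)]
        pwm, _ = mo.build_pwm(kmers)
        np.testing.assert_allclose(pwm.sum(axis=1), 1.0, atol=1e-12)


class TestActivityAndEffect:
    def test_constant_activation_constant_activity(self):
        acts = np.full((6, 40, 3), 2.5, dtype=np.float32)
        table = mo.motif_activity(acts)
        assert table.shape == (3, 6)
        np.testing.assert_allclose(table.mean, 2.5)
        np.testing.assert_allclose(table.max, 2.5)

    def test_mean_matches_recomputation(self, dna_model, rng):
        windows = rng.integers(0, 2, (9, 61, 4)).astype(np.float32)
        acts = mo.filter_activations(dna_model, windows)
        table = mo.motif_activity(acts)
        for f, w in [(0, 0), (3, 5), (7, 8)]:
            assert table.mean[f, w] == pytest.approx(
                float(np.mean(acts[w, :, f])), rel=1e-6)

    def test_effect_is_one_when_activity_equals_labels(self):
        labels = np.array([1.0, 0, 1, 0, 1, 0])
        table = mo.ActivityTable(mean=np.vstack([labels, 1 - labels]),
                                 max=np.zeros((2, 6)), labels=labels)
        effects = mo.motif_effect(table)
        assert effects[0] == pytest.approx(1.0)
        assert effects[1] == pytest.approx(-1.0)

    def test_independent_activity_small_effect(self, rng):
        labels = rng.integers(0, 2, 1000).astype(float)
        table = mo.ActivityTable(mean=rng.random((5, 1000)),
                                 max=np.zeros((5, 1000)), labels=labels)
        assert np.abs(mo.motif_effect(table)).max() < 0.1

    def test_zero_variance_filter_gets_zero_effect(self):
        labels = np.array([1.0, 0, 1, 0])
        table = mo.ActivityTable(mean=np.full((2, 4), 3.0),
                                 max=np.zeros((2, 4)), labels=labels)
        np.testing.assert_array_equal(mo.motif_effect(table), 0.0)


class TestPca:
    def eigen_oracle(self, A):
        """From-scratch eigendecomposition of the feature covariance."""
        X = A - A.mean(axis=0)
        C = X.T @ X / (len(A) - 1)
        vals, vecs = np.linalg.eigh(C)
        order = np.argsort(vals)[::-1]
        return X @ vecs[:, order[:2]]

    def test_matches_spectral_oracle_up_to_sign(self, rng):
        A = rng.random((5, 20))
        table = mo.ActivityTable(mean=A, max=A)
        got = mo.pca_motifs(table)
        want = self.eigen_oracle(A)
        for j in range(2):
            agree = np.allclose(got[:, j], want[:, j], atol=1e-8)
            flipped = np.allclose(got[:, j], -want[:, j], atol=1e-8)
            assert agree or flipped

    def test_duplicated_filters_identical_coordinates(self, rng):
        A = rng.random((6, 15))
        A[3] = A[1]
        coords = mo.pca_motifs(mo.ActivityTable(mean=A, max=A))
        np.testing.assert_allclose(coords[1], coords[3], atol=1e-10)

    def test_component_variances_non_increasing_and_uncorrelated(self, rng):
        A = rng.random((30, 50))
        coords = mo.pca_motifs(mo.ActivityTable(mean=A, max=A))
        cov = np.cov(coords.T)
        assert cov[0, 0] >= cov[1, 1]
        assert abs(cov[0, 1]) < 1e-10

    def test_sign_convention_is_deterministic(self, rng):
        A = rng.random((8, 12))
        a = mo.pca_motifs(mo.ActivityTable(mean=A, max=A))
        b = mo.pca_motifs(mo.ActivityTable(mean=A.copy(), max=A.copy()))
        np.testing.assert_array_equal(a, b)

    def test_too_few_filters_rejected(self, rng):
        A = rng.random((2, 10))
        with pytest.raises(ValueError, match="at least 3"):
            mo.pca_motifs(mo.ActivityTable(mean=A, max=A))


class TestMatchCorrelation:
    def test_exact_consensus_is_perfect_match(self):
        pwm = mo.consensus_pwm("AATTATTTAAT")
        assert mo.pwm_match_correlation(pwm, "AATTATTTAAT") == pytest.approx(1.0)

    def test_shifted_and_reverse_complement_still_match(self):
        c = "AATTATCCAAT"
        pwm = mo.consensus_pwm(c)
        shifted = np.vstack([np.full((2, 4), 0.25), pwm[:-2]])
        assert mo.pwm_match_correlation(shifted, c) > 0.75
        rc = pwm[::-1, [3, 2, 1, 0]]
        assert mo.pwm_match_correlation(rc, c) == pytest.approx(1.0)

    def test_uniform_pwm_matches_nothing(self):
        uniform = np.full((11, 4), 0.25)
        assert mo.pwm_match_correlation(uniform, "AATTATTTAAT") < 0.2


def test_extract_motifs_end_to_end(dna_model, rng):
    windows = rng.integers(0, 2, (12, 61, 4)).astype(np.float32)
    labels = rng.integers(0, 2, 12).astype(float)
    ms = mo.extract_motifs(dna_model, windows, labels=labels)
    assert len(ms) == 8
    frame = ms.to_frame()
    assert set(frame.columns) >= {"filter", "consensus", "n_windows", "ic",
                                  "effect", "pc1", "pc2"}
    for m in ms:
        np.testing.assert_allclose(m.pwm.sum(axis=1), 1.0, atol=1e-9)
        assert m.ic >= 0
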